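"""Pairwise genetic distances on genotype-code matrices with missing data.

All pairwise statistics are computed over pairwise-complete sites (both
samples called) using indicator algebra, so no loops over sample pairs are
needed.
"""

from __future__ import annotations

import numpy as np

from .panel import GenotypePanel, MISSING, PanelError

__all__ = [
    "pairwise_sums",
    "squared_distance_matrix",
    "allele_sharing_distance",
]


def pairwise_sums(panel: GenotypePanel):
    """Return (ss, abs_sum, n_complete) between all sample pairs.

    ``ss[i, j]``       = sum over pairwise-complete sites of (x_i - x_j)^2
    ``abs_sum[i, j]``  = sum of |x_i - x_j|
    ``n_complete[i,j]``= number of pairwise-complete sites
    """
    X = panel.calls.astype(np.float64)
    called = panel.called_mask().astype(np.float64)
    V = np.where(panel.calls == MISSING, 0.0, X)
    V2C = (V * V) @ called.T
    cross = V @ V.T
    ss = V2C - 2.0 * cross + V2C.T
    # |a-b| differs from (a-b)^2 only where {a, b} = {0, 2}: there it is 2, not 4
    zero = ((panel.calls == 0)).astype(np.float64)
    two = ((panel.calls == 2)).astype(np.float64)
    n_02 = zero @ two.T
    count4 = n_02 + n_02.T
    abs_sum = ss - 2.0 * count4
    n_complete = called @ called.T
    return ss, abs_sum, n_complete


def squared_distance_matrix(panel: GenotypePanel) -> np.ndarray:
    """Pairwise squared Euclidean distance over genotype codes, rescaled per
    pair by (total sites / pairwise-complete sites) to correct for
    missingness.  A pair sharing zero called sites is an error."""
    if panel.n_samples < 2:
        raise PanelError("need >= 2 samples")
    ss, _, n_complete = pairwise_sums(panel)
    off = ~np.eye(panel.n_samples, dtype=bool)
    if (n_complete[off] == 0).any():
        i, j = np.argwhere((n_complete == 0) & off)[0]
        raise PanelError(
            f"samples {panel.sample_ids[i]!r} and {panel.sample_ids[j]!r} "
            "share no called sites"
        )
    d2 = ss * (panel.n_sites / n_complete)
    np.fill_diagonal(d2, 0.0)
    return d2


def allele_sharing_distance(panel: GenotypePanel) -> np.ndarray:
    """1 - proportion of shared alleles, averaged over pairwise-complete
    sites; in [0, 1], zero diagonal."""
    _, abs_sum, n_complete = pairwise_sums(panel)
    off = ~np.eye(panel.n_samples, dtype=bool)
    if (n_complete[off] == 0).any():
        raise PanelError("some sample pair shares no called sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = abs_sum / (2.0 * np.maximum(n_complete, 1))
    np.fill_diagonal(d, 0.0)
    return d
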