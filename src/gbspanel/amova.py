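"""Distance-based analysis of molecular variance (AMOVA) with PhiPT.

Two-level AMOVA in the Excoffier tradition as popularised by GenAlEx: each
sample is an individual, total molecular variance is partitioned into among-
and within-group components from squared pairwise distances, and PhiPT (an
FST analogue ignoring within-individual variation) is the among-group share:

    SS_total  = sum_{i<j} d2_ij / N
    SS_within = sum_g sum_{i<j in g} d2_ij / n_g
    SS_among  = SS_total - SS_within
    MS        = SS / df,   df_among = k - 1,  df_within = N - k
    n0        = (N - sum_g n_g^2 / N) / (k - 1)
    var_within = MS_within
    var_among  = max(0, (MS_among - MS_within) / n0)
    PhiPT      = var_among / (var_among + var_within)

Significance comes from permuting group labels; the reported p-value uses
the (hits + 1) / (n_perm + 1) correction.  Per-group nucleotide diversity
(pi) is the expected per-site heterozygosity of two alleles drawn without
replacement within the group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import squared_distance_matrix
from .panel import GenotypePanel, PanelError

log = logging.getLogger(__name__)

__all__ = [
    "AmovaResult",
    "amova_from_ss",
    "amova",
    "pairwise_phipt",
    "nucleotide_diversity",
    "squared_distance_matrix",
]


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    phi_pt: float
    n0: float
    perm_p: float | None = None

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    def to_frame(self) -> pd.DataFrame:
        """Conventional AMOVA table layout (SV, df, SS, MS, Est. var., %, PhiPT)."""
        return pd.DataFrame(
            [
                {
                    "SV": "Among groups",
                    "df": self.df_among,
                    "SS": self.ss_among,
                    "MS": self.ms_among,
                    "Est. var.": self.var_among,
                    "%": self.pct_among,
                    "PhiPT": self.phi_pt,
                },
                {
                    "SV": "Within groups",
                    "df": self.df_within,
                    "SS": self.ss_within,
                    "MS": self.ms_within,
                    "Est. var.": self.var_within,
                    "%": self.pct_within,
                    "PhiPT": np.nan,
                },
                {
                    "SV": "Total",
                    "df": self.df_among + self.df_within,
                    "SS": self.ss_total,
                    "MS": np.nan,
                    "Est. var.": self.var_among + self.var_within,
                    "%": 100.0,
                    "PhiPT": np.nan,
                },
            ]
        )


def amova_from_ss(
    ss_among: float,
    ss_within: float,
    df_among: int,
    df_within: int,
    group_sizes,
) -> AmovaResult:
    """Variance components, percentages and PhiPT from sums of squares.

    ``n0`` is the weighted average group-size coefficient
    (N - sum n_i^2 / N) / (k - 1); a negative among-group component is
    clamped to zero.
    """
    sizes = np.asarray(list(group_sizes), dtype=float)
    if df_among <= 0 or df_within <= 0:
        raise PanelError("degrees of freedom must be positive")
    if (sizes <= 0).any():
        raise PanelError("group sizes must be positive")
    N = sizes.sum()
    k = len(sizes)
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    if n0 <= 0:
        raise PanelError(f"degenerate group sizes: n0 = {n0}")
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    var_within = ms_within
    var_among = max(0.0, (ms_among - ms_within) / n0)
    total = var_among + var_within
    phi = var_among / total if total > 0 else 0.0
    return AmovaResult(
        df_among=int(df_among),
        df_within=int(df_within),
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        ms_among=ms_among,
        ms_within=ms_within,
        var_among=var_among,
        var_within=var_within,
        pct_among=100.0 * var_among / total if total > 0 else 0.0,
        pct_within=100.0 * var_within / total if total > 0 else 100.0,
        phi_pt=phi,
        n0=float(n0),
    )


def _ss_partition(d2: np.ndarray, labels: np.ndarray):
    """(ss_among, ss_within) from a squared-distance matrix and labels."""
    N = d2.shape[0]
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total - ss_within, ss_within


def _phi_unclamped(d2: np.ndarray, labels: np.ndarray) -> float:
    """PhiPT without the negative-component clamp.

    The permutation test compares this raw statistic between the observed
    and permuted labelings: the clamp would collapse every under-dispersed
    labeling onto zero and destroy the uniformity of null p-values.
    """
    sizes = np.array([int((labels == g).sum()) for g in np.unique(labels)], dtype=float)
    k = len(sizes)
    N = d2.shape[0]
    ss_among, ss_within = _ss_partition(d2, labels)
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    var_among = (ms_among - ms_within) / n0
    total = var_among + ms_within
    return var_among / total if total != 0 else 0.0


def amova(
    data,
    labels,
    n_perm: int = 999,
    seed: int = 42,
) -> AmovaResult:
    """Two-level distance AMOVA.

    ``data`` is a GenotypePanel (squared distances computed with
    missingness rescaling) or a precomputed squared-distance matrix.
    Every group needs >= 2 members.  With ``n_perm > 0`` a permutation
    p-value for PhiPT is attached (proportion of label permutations with
    PhiPT >= observed, (hits+1)/(n_perm+1)).
    """
    labels = np.asarray(labels)
    d2 = (
        squared_distance_matrix(data)
        if isinstance(data, GenotypePanel)
        else np.asarray(data, dtype=float)
    )
    N = d2.shape[0]
    if labels.shape[0] != N:
        raise PanelError("labels do not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise PanelError("need >= 2 groups")
    if (counts < 2).any():
        raise PanelError(
            f"singleton groups not allowed: {uniq[counts < 2].tolist()}"
        )
    ss_among, ss_within = _ss_partition(d2, labels)
    result = amova_from_ss(ss_among, ss_within, len(uniq) - 1, N - len(uniq), counts)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        observed = _phi_unclamped(d2, labels)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if _phi_unclamped(d2, perm) >= observed:
                hits += 1
        result.perm_p = (hits + 1) / (n_perm + 1)
    return result


def pairwise_phipt(
    panel_or_d2,
    labels,
    n_perm: int = 0,
    seed: int = 42,
):
    """PhiPT (and optional permutation p) for every group pair.

    Returns (phi DataFrame, p DataFrame or None); matrices are symmetric
    with zero/NaN diagonals.  Each pair is analysed as its own two-group
    AMOVA restricted to the pair's samples.
    """
    labels = np.asarray(labels)
    d2 = (
        squared_distance_matrix(panel_or_d2)
        if isinstance(panel_or_d2, GenotypePanel)
        else np.asarray(panel_or_d2, dtype=float)
    )
    groups = list(pd.unique(labels))
    phi = pd.DataFrame(0.0, index=groups, columns=groups)
    pval = pd.DataFrame(np.nan, index=groups, columns=groups) if n_perm else None
    for ga, gb in itertools.combinations(groups, 2):
        idx = np.where((labels == ga) | (labels == gb))[0]
        sub = d2[np.ix_(idx, idx)]
        res = amova(sub, labels[idx], n_perm=n_perm, seed=seed)
        phi.loc[ga, gb] = phi.loc[gb, ga] = res.phi_pt
        if n_perm:
            pval.loc[ga, gb] = pval.loc[gb, ga] = res.perm_p
    return phi, pval


def nucleotide_diversity(panel: GenotypePanel, labels) -> pd.Series:
    """Per-group mean per-site nucleotide diversity.

    Within a group, pi at a site with m called alleles of which j are
    alternate is 2 j (m - j) / (m (m - 1)); the group value is the mean over
    sites with m >= 2 (others skipped with a logged count).
    """
    labels = np.asarray(labels)
    out = {}
    for g in pd.unique(labels):
        mask = labels == g
        if mask.sum() < 2:
            raise PanelError(f"group {g!r} needs >= 2 members")
        alt, m = panel.allele_counts(mask)
        ok = m >= 2
        if (~ok).any():
            log.info("group %r: %d sites with < 2 called alleles skipped", g, int((~ok).sum()))
        j, mm = alt[ok].astype(float), m[ok].astype(float)
        pi = 2.0 * j * (mm - j) / (mm * (mm - 1.0))
        out[g] = float(pi.mean()) if pi.size else float("nan")
    return pd.Series(out, name="pi")
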