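"""Hierarchical species-diagnostic SNP discovery.

At each node of a nested discrimination tree, every SNP is tested for an
allele-frequency contrast between two taxon sets with Pearson's chi-square
(no continuity correction) on the 2x2 allele-count table built from called
alleles only; sites with any zero marginal score 0 with p = 1.  Retained
markers (adjusted p below alpha) form the node's diagnostic panel, reported
with per-chromosome counts and verified by a PCoA restricted to the panel,
whose first-two-component explained variances and silhouette-style
separation score are attached.

A genotype-count granularity (3x2 table over dosage classes) is available
as an option; allele counts are the default as they maximise power for
fixed-difference signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .panel import GenotypePanel, PanelError, SiteAnnotations
from .structure import pcoa, relationship_matrix

__all__ = [
    "DiscriminationNode",
    "DiscriminationTree",
    "load_wheat_tree",
    "snp_chi_square",
    "chi_square_scan",
    "DiagnosticSNPSelector",
    "NodePanel",
    "discriminant_panel",
    "run_hierarchy",
    "verify_node_pcoa",
]


# ---------------------------------------------------------------------------
# tree specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscriminationNode:
    """One contrast: taxon-label set A versus set B, nested under a parent."""

    id: str
    side_a: tuple
    side_b: tuple
    parent: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "side_a", tuple(self.side_a))
        object.__setattr__(self, "side_b", tuple(self.side_b))
        if not self.side_a or not self.side_b:
            raise PanelError(f"node {self.id}: contrast sides must be nonempty")
        if set(self.side_a) & set(self.side_b):
            raise PanelError(f"node {self.id}: contrast sides overlap")

    @property
    def scope(self) -> frozenset:
        return frozenset(self.side_a) | frozenset(self.side_b)


@dataclass
class DiscriminationTree:
    """Parent-first list of nodes; child scopes must nest in their parent's."""

    nodes: list
    label_on: str = "species_subspecies"

    def __post_init__(self):
        seen: dict[str, DiscriminationNode] = {}
        for node in self.nodes:
            if node.id in seen:
                raise PanelError(f"duplicate node id {node.id!r}")
            if node.parent is not None:
                if node.parent not in seen:
                    raise PanelError(
                        f"node {node.id}: parent {node.parent!r} must precede it"
                    )
                if not node.scope <= seen[node.parent].scope:
                    raise PanelError(
                        f"node {node.id}: scope is not nested in parent {node.parent}"
                    )
            seen[node.id] = node

    @classmethod
    def from_yaml(cls, path_or_stream) -> "DiscriminationTree":
        if hasattr(path_or_stream, "read"):
            spec = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                spec = yaml.safe_load(fh)
        nodes = [
            DiscriminationNode(
                id=str(n["id"]),
                side_a=tuple(n["side_a"]),
                side_b=tuple(n["side_b"]),
                parent=None if n.get("parent") is None else str(n["parent"]),
            )
            for n in spec["nodes"]
        ]
        return cls(nodes=nodes, label_on=spec.get("label_on", "species_subspecies"))


def load_wheat_tree() -> DiscriminationTree:
    """The packaged four-level common/durum wheat discrimination tree."""
    with resources.files("gbspanel.data").joinpath(
        "wheat_discrimination_tree.yaml"
    ).open() as fh:
        return DiscriminationTree.from_yaml(fh)


# ---------------------------------------------------------------------------
# chi-square machinery
# ---------------------------------------------------------------------------

def chi_square_scan(
    panel: GenotypePanel,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    granularity: str = "allele",
):
    """Per-site Pearson chi-square contrasting two sample sets.

    Returns (statistic, p, low_expected) arrays over all sites.  With
    ``granularity='allele'`` the 2x2 table is allele {ref, alt} x side; any
    zero marginal gives statistic 0, p 1.  ``low_expected`` flags tables
    with an expected cell below 5 (Cochran's adequacy rule), where the
    asymptotic p-value is unreliable.  With ``granularity='genotype'`` a 3x2
    dosage-class table is used (df = nonzero dosage rows - 1).
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if granularity == "allele":
        alt_a, m_a = panel.allele_counts(mask_a)
        alt_b, m_b = panel.allele_counts(mask_b)
        ref_a, ref_b = m_a - alt_a, m_b - alt_b
        N = (m_a + m_b).astype(float)
        r1, r2 = (ref_a + ref_b).astype(float), (alt_a + alt_b).astype(float)
        c1, c2 = m_a.astype(float), m_b.astype(float)
        det = ref_a * alt_b - alt_a * ref_b
        denom = r1 * r2 * c1 * c2
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(denom > 0, N * det.astype(float) ** 2 / np.maximum(denom, 1), 0.0)
        p = np.where(denom > 0, stats.chi2.sf(stat, df=1), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            min_exp = np.minimum.reduce(
                [r1 * c1, r1 * c2, r2 * c1, r2 * c2]
            ) / np.maximum(N, 1)
        low_expected = (denom > 0) & (min_exp < 5.0)
        return stat, p, low_expected

    if granularity != "genotype":
        raise ValueError("granularity must be 'allele' or 'genotype'")
    counts = []  # per side, per dosage class: (n_sites,) counts
    for mask in (mask_a, mask_b):
        calls = panel.calls[mask]
        counts.append(np.stack([(calls == g).sum(axis=0) for g in (0, 1, 2)]))
    O = np.stack(counts, axis=-1).astype(float)  # (3 dosage, n_sites, 2 sides)
    row = O.sum(axis=-1)  # (3, n_sites)
    col = O.sum(axis=0)  # (n_sites, 2)
    N = col.sum(axis=-1)  # (n_sites,)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = row[:, :, None] * col[None, :, :] / np.maximum(N, 1)[None, :, None]
        term = np.where(E > 0, (O - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
    stat = term.sum(axis=(0, 2))
    nonzero_rows = (row > 0).sum(axis=0)
    df = np.maximum(nonzero_rows - 1, 0)
    ok = (df > 0) & (col > 0).all(axis=-1)
    stat = np.where(ok, stat, 0.0)
    p = np.where(ok, stats.chi2.sf(stat, df=np.maximum(df, 1)), 1.0)
    low_expected = ok & (np.where(E > 0, E, np.inf).min(axis=(0, 2)) < 5.0)
    return stat, p, low_expected


def snp_chi_square(panel: GenotypePanel, side_a, side_b, site: int):
    """(statistic, p) for a single site; ``side_a``/``side_b`` are sample-id
    lists or boolean masks.  Both sides need at least one called sample."""
    mask_a = _side_mask(panel, side_a)
    mask_b = _side_mask(panel, side_b)
    sub = panel.subset_sites(np.array([site]))
    for name, mask in (("a", mask_a), ("b", mask_b)):
        if (sub.calls[mask] != -1).sum() == 0:
            raise PanelError(f"site {site}: no called samples on side {name}")
    stat, p, _ = chi_square_scan(sub, mask_a, mask_b)
    return float(stat[0]), float(p[0])


def _side_mask(panel: GenotypePanel, side) -> np.ndarray:
    side = np.asarray(side)
    if side.dtype == bool:
        return side
    wanted = set(side.tolist())
    return np.array([s in wanted for s in panel.sample_ids])


class DiagnosticSNPSelector(SelectorMixin, BaseEstimator):
    """Feature selector retaining SNPs whose allele frequencies differ
    between two classes by Pearson chi-square at adjusted p < alpha.

    ``X`` is a samples x sites dosage matrix (-1 for missing), ``y`` a
    two-class label vector.  ``correction`` is 'bonferroni', 'fdr_bh' or
    'none'.  Fitted attributes: ``statistic_``, ``pvalues_``,
    ``pvalues_adjusted_``, ``low_expected_``, ``support_``.
    """

    def __init__(self, alpha: float = 0.05, correction: str = "bonferroni",
                 granularity: str = "allele"):
        self.alpha = alpha
        self.correction = correction
        self.granularity = granularity

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise PanelError(f"need exactly 2 classes, got {len(classes)}")
        sites = pd.DataFrame(
            {"chrom": ["0"] * X.shape[1], "pos": np.arange(1, X.shape[1] + 1)}
        )
        tmp = GenotypePanel(X.astype(np.int8), [f"s{i}" for i in range(len(X))], sites)
        stat, p, low = chi_square_scan(
            tmp, y == classes[0], y == classes[1], self.granularity
        )
        self.statistic_ = stat
        self.pvalues_ = p
        self.pvalues_adjusted_ = adjust_pvalues(p, self.correction)
        self.low_expected_ = low
        self.support_ = self.pvalues_adjusted_ < self.alpha
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_


def adjust_pvalues(p: np.ndarray, correction: str = "bonferroni") -> np.ndarray:
    if correction in (None, "none"):
        return np.asarray(p, dtype=float)
    method = {"bonferroni": "bonferroni", "fdr_bh": "fdr_bh"}.get(correction)
    if method is None:
        raise ValueError(f"unknown correction {correction!r}")
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# node panels and the hierarchy
# ---------------------------------------------------------------------------

@dataclass
class NodePanel:
    """Diagnostic-SNP panel of one tree node."""

    node_id: str
    table: pd.DataFrame  # chrom, pos, ref, alt, statistic, p, p_adj, low_expected
    n_side_a: int
    n_side_b: int
    ftpc: tuple | None = None  # first-two-component explained variance (%)
    separation: float | None = None
    per_chrom: pd.Series = field(default=None, repr=False)

    def __post_init__(self):
        if self.per_chrom is None:
            self.per_chrom = self.table.groupby("chrom").size()

    @property
    def n_snps(self) -> int:
        return len(self.table)


def discriminant_panel(
    panel: GenotypePanel,
    node: DiscriminationNode,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    ann: SiteAnnotations | None = None,
    label_on: str = "species_subspecies",
    granularity: str = "allele",
) -> NodePanel:
    """Test every SNP at one node and keep those with adjusted p < alpha.

    The node's sample scope is the union of its contrast sides; output rows
    are ordered by (chrom, pos)."""
    labels = panel.taxon_labels(label_on)
    mask_a = np.isin(labels, node.side_a)
    mask_b = np.isin(labels, node.side_b)
    for side, mask in (("A", mask_a), ("B", mask_b)):
        if not mask.any():
            raise PanelError(
                f"node {node.id}: contrast side {side} matches no samples"
            )
    stat, p, low = chi_square_scan(panel, mask_a, mask_b, granularity)
    p_adj = adjust_pvalues(p, correction)
    keep = p_adj < alpha
    table = panel.sites.loc[keep, ["chrom", "pos"]].reset_index(drop=True)
    if ann is not None:
        ann.check_aligned(panel)
        table["ref"] = ann.df.loc[keep, "ref"].to_numpy()
        table["alt"] = ann.df.loc[keep, "alt"].to_numpy()
    table["statistic"] = stat[keep]
    table["p"] = p[keep]
    table["p_adj"] = p_adj[keep]
    table["low_expected"] = low[keep]
    table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return NodePanel(
        node_id=node.id,
        table=table,
        n_side_a=int(mask_a.sum()),
        n_side_b=int(mask_b.sum()),
    )


def run_hierarchy(
    panel: GenotypePanel,
    tree: DiscriminationTree,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    ann: SiteAnnotations | None = None,
    verify: bool = False,
) -> list:
    """Traverse the tree parent-first, building each node's panel on its own
    sample scope; optionally attach the PCoA verification to each panel.
    The aggregate diagnostic count is the sum over node panels."""
    panels = []
    for node in tree.nodes:
        node_panel = discriminant_panel(
            panel, node, alpha=alpha, correction=correction, ann=ann,
            label_on=tree.label_on,
        )
        if verify:
            verify_node_pcoa(panel, node_panel, node, label_on=tree.label_on)
        panels.append(node_panel)
    return panels


def verify_node_pcoa(
    panel: GenotypePanel,
    node_panel: NodePanel,
    node: DiscriminationNode,
    label_on: str = "species_subspecies",
):
    """PCoA restricted to the node's SNPs and sample scope.

    Returns (ftpc1_pct, ftpc2_pct, separation) and stores them on the
    NodePanel; separation is the silhouette score of the contrast sides on
    the first two principal coordinates.  With fewer than 2 panel SNPs the
    score is undefined (None) and a warning is issued.
    """
    if node_panel.n_snps < 2:
        warnings.warn(f"node {node.id}: panel has < 2 SNPs; separation undefined")
        node_panel.ftpc = None
        node_panel.separation = None
        return None
    labels = panel.taxon_labels(label_on)
    scope = np.isin(labels, tuple(node.scope))
    keys = set(zip(node_panel.table["chrom"], node_panel.table["pos"]))
    site_mask = np.array([key in keys for key in panel.site_keys()])
    sub = panel.subset_samples(scope).subset_sites(site_mask)
    ord_ = pcoa(relationship_matrix(sub))
    ev = ord_.explained_variance_ratio_
    ftpc = (
        100.0 * float(ev[0]),
        100.0 * float(ev[1]) if len(ev) > 1 else 0.0,
    )
    coords = ord_.coordinates_[:, : min(2, ord_.coordinates_.shape[1])]
    side = np.isin(labels[scope], node.side_a).astype(int)
    sep = float(silhouette_score(coords, side)) if len(np.unique(side)) == 2 else None
    node_panel.ftpc = ftpc
    node_panel.separation = sep
    return ftpc[0], ftpc[1], sep
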