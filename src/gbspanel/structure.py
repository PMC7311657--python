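"""Population-structure analysis: relationship matrix, principal coordinate
analysis, BIC-guided cluster finding, discriminant analysis of principal
components (DAPC), and a neighbor-joining tree with Newick export.

The estimators follow scikit-learn conventions (``fit``, fitted attributes
with a trailing underscore) and compose with sklearn model selection; the
module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .distance import allele_sharing_distance, squared_distance_matrix  # noqa: F401
from .panel import GenotypePanel, MISSING, PanelError

log = logging.getLogger(__name__)

__all__ = [
    "relationship_matrix",
    "impute_codes",
    "PCoA",
    "pcoa",
    "ClusterFinder",
    "find_clusters",
    "DAPC",
    "nj_tree",
]


def relationship_matrix(panel: GenotypePanel) -> np.ndarray:
    """Standardized genetic relationship matrix (GRM).

    Each site is centred by twice its alternate-allele frequency and scaled
    by sqrt(2 p q) (the Hardy-Weinberg standard deviation of the dosage);
    the cross-product is averaged over pairwise-complete sites, so missing
    calls drop out pair by pair.  Monomorphic (zero-variance) sites are
    skipped with a logged count.
    """
    if panel.n_samples < 2:
        raise PanelError("need >= 2 samples")
    p = panel.alt_frequency()
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    n_skipped = panel.n_sites - int(usable.sum())
    if n_skipped:
        log.info("relationship_matrix: skipping %d zero-variance sites", n_skipped)
    if not usable.any():
        raise PanelError("no polymorphic sites")
    X = panel.calls[:, usable].astype(np.float64)
    called = (panel.calls[:, usable] != MISSING).astype(np.float64)
    p = p[usable]
    W = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    W = np.where(called > 0, W, 0.0)
    counts = called @ called.T
    if (counts == 0).any():
        raise PanelError("some sample pair shares no called polymorphic sites")
    K = (W @ W.T) / counts
    return (K + K.T) / 2.0


def impute_codes(panel: GenotypePanel) -> np.ndarray:
    """Genotype codes with missing calls mean-imputed per site (ordination
    use only; never used for AMOVA or chi-square tests)."""
    X = panel.calls.astype(np.float64)
    X[panel.calls == MISSING] = np.nan
    means = np.nanmean(X, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[1]]
    return X


class PCoA(TransformerMixin, BaseEstimator):
    """Principal coordinate analysis of a symmetric relationship matrix.

    Eigen-decomposition with components ordered by eigenvalue; sample
    coordinates are eigenvectors scaled by sqrt(eigenvalue) for the
    positive spectrum.  Explained variance is eigenvalue over the sum of
    positive eigenvalues.  For reproducibility the sign of each component
    is fixed so its largest-magnitude loading is positive.

    Attributes (after fit): ``coordinates_``, ``eigenvalues_``,
    ``explained_variance_ratio_``, ``eigenvectors_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        K = np.asarray(X, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise PanelError("PCoA needs a square matrix")
        if not np.allclose(K, K.T, atol=1e-8):
            raise PanelError("PCoA needs a symmetric matrix")
        evals, evecs = np.linalg.eigh((K + K.T) / 2.0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        pos = evals > 1e-12
        if not pos.any():
            raise PanelError("invalid relationship matrix: no positive eigenvalues")
        n_keep = int(pos.sum())
        if self.n_components is not None:
            n_keep = min(n_keep, self.n_components)
        evals_k, evecs_k = evals[:n_keep], evecs[:, :n_keep]
        # sign convention: largest-|loading| entry of each axis positive
        for j in range(n_keep):
            i = np.argmax(np.abs(evecs_k[:, j]))
            if evecs_k[i, j] < 0:
                evecs_k[:, j] = -evecs_k[:, j]
        self.eigenvalues_ = evals_k
        self.eigenvectors_ = evecs_k
        self.coordinates_ = evecs_k * np.sqrt(evals_k)
        self.explained_variance_ratio_ = evals_k / evals[evals > 0].sum()
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).coordinates_

    def transform(self, X):  # PCoA is sample-bound; only fit_transform is meaningful
        raise NotImplementedError("PCoA coordinates exist only for fitted samples")


def pcoa(matrix: np.ndarray, n_components: int | None = None) -> PCoA:
    """Fit a :class:`PCoA` on a relationship matrix and return it."""
    return PCoA(n_components=n_components).fit(matrix)


class ClusterFinder(ClusterMixin, BaseEstimator):
    """BIC-guided k-means over retained ordination axes.

    For each k in 1..k_max a multi-restart k-means is fitted on the retained
    ordination axes (all of them by default, the convention of the adegenet
    find.clusters default; ``n_pcs`` restricts to the leading axes) and
    scored by BIC(k) = n ln(WSS_k / n) + k ln(n); the
    selected k minimises BIC (an explicit ``k_override`` is available for
    elbow-style manual choice).

    Attributes (after fit): ``labels_`` (contiguous 1..k), ``k_``,
    ``bic_`` (pandas Series over candidate k), ``all_labels_``.
    """

    def __init__(self, k_max: int = 10, n_pcs: int | None = None, random_state: int = 42,
                 n_init: int = 20, max_iter: int = 300, k_override: int | None = None):
        self.k_max = k_max
        self.n_pcs = n_pcs
        self.random_state = random_state
        self.n_init = n_init
        self.max_iter = max_iter
        self.k_override = k_override

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.k_max < 1:
            raise PanelError("k_max must be >= 1")
        if self.k_max > n:
            raise PanelError(f"k_max={self.k_max} exceeds n_samples={n}")
        Z = X if self.n_pcs is None else X[:, : self.n_pcs]
        bic = {}
        labels = {}
        for k in range(1, self.k_max + 1):
            if k == 1:
                wss = float(((Z - Z.mean(axis=0)) ** 2).sum())
                lab = np.zeros(n, dtype=int)
            else:
                km = KMeans(
                    n_clusters=k,
                    n_init=self.n_init,
                    max_iter=self.max_iter,
                    random_state=self.random_state,
                ).fit(Z)
                wss = float(km.inertia_)
                lab = km.labels_
            bic[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
            labels[k] = lab + 1
        self.bic_ = pd.Series(bic, name="BIC")
        self.all_labels_ = labels
        self.k_ = int(self.k_override or self.bic_.idxmin())
        self.labels_ = labels[self.k_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def find_clusters(panel: GenotypePanel, k_max: int = 10, n_pcs: int | None = None,
                  seed: int = 42) -> ClusterFinder:
    """Relationship matrix -> PCoA -> BIC-guided k-means on a panel."""
    coords = pcoa(relationship_matrix(panel)).coordinates_
    return ClusterFinder(k_max=k_max, n_pcs=n_pcs, random_state=seed).fit(coords)


class DAPC(ClassifierMixin, BaseEstimator):
    """Discriminant analysis of principal components.

    Dimensionality reduction (PCA on mean-imputed genotype codes, ``n_pcs``
    axes retained) followed by linear discriminant analysis maximising
    between- over within-cluster variance; at most k-1 discriminant
    functions are kept.

    Attributes (after fit): ``n_discriminants_``, ``eigenvalues_``
    (discriminant variance ratios, nonincreasing), ``pc_variance_ratio_``
    (fraction of total variance the retained PCs conserve), ``classes_``.
    """

    def __init__(self, n_pcs: int = 30, n_da: int | None = None,
                 random_state: int = 42):
        self.n_pcs = n_pcs
        self.n_da = n_da
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if (counts < 2).any():
            bad = classes[counts < 2].tolist()
            raise PanelError(
                f"clusters with a single member: {bad}; within-group scatter "
                "is singular -- merge these clusters first"
            )
        if self.n_pcs > X.shape[0] - 1:
            raise PanelError("n_pcs must be <= n_samples - 1")
        k = len(classes)
        n_da = min(self.n_da or k - 1, k - 1)
        self.pca_ = PCA(n_components=self.n_pcs, random_state=self.random_state)
        scores = self.pca_.fit_transform(X)
        self.lda_ = LinearDiscriminantAnalysis(n_components=n_da)
        self.lda_.fit(scores, y)
        self.classes_ = self.lda_.classes_
        self.n_discriminants_ = n_da
        ev = np.asarray(self.lda_.explained_variance_ratio_[:n_da])
        self.eigenvalues_ = ev
        self.pc_variance_ratio_ = float(self.pca_.explained_variance_ratio_.sum())
        return self

    def transform(self, X):
        """Discriminant coordinates of samples."""
        return self.lda_.transform(self.pca_.transform(np.asarray(X, dtype=float)))

    def predict(self, X):
        return self.lda_.predict(self.pca_.transform(np.asarray(X, dtype=float)))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def dapc_cross_validate(X, y, n_pcs_grid=None, cv: int = 5, seed: int = 42) -> pd.DataFrame:
    """Held-out assignment accuracy across candidate numbers of retained PCs
    (the cross-validation used to choose ``n_pcs``).  Returns a DataFrame
    with columns ``n_pcs`` and ``accuracy``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_pcs_grid is None:
        hi = min(X.shape[0] - 2, X.shape[1], 60)
        n_pcs_grid = sorted({max(2, hi // 4), max(3, hi // 2), hi})
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(cv, counts.min()))
    if n_splits < 2:
        raise PanelError("cross-validation needs every cluster to have >= 2 members")
    rows = []
    for n_pcs in n_pcs_grid:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        accs = []
        for train, test in skf.split(X, y):
            model = DAPC(n_pcs=min(n_pcs, len(train) - 1), random_state=seed)
            model.fit(X[train], y[train])
            accs.append(model.score(X[test], y[test]))
        rows.append({"n_pcs": n_pcs, "accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)


def _quote(label: str) -> str:
    if any(c in label for c in " \t()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick(node: _Node) -> str:
    if not node.children:
        return _quote(str(node.label))
    inner = ",".join(f"{_newick(ch)}:{bl:.17g}" for ch, bl in node.children)
    label = _quote(str(node.label)) if node.label else ""
    return f"({inner}){label}"


def nj_tree(dist: np.ndarray, labels: list[str]) -> str:
    """Standard neighbor joining on a symmetric distance matrix; returns a
    Newick string.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sister branch of the join, preserving the pairwise distance
    between the joined taxa.  Fewer than 3 taxa yield a trivial tree with a
    warning.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or len(labels) != n:
        raise PanelError("distance matrix and labels disagree")
    if not np.allclose(D, D.T, atol=1e-8) or (np.diag(D) != 0).any() or (D < -1e-12).any():
        raise PanelError("need a symmetric, nonnegative, zero-diagonal matrix")
    if n == 0:
        raise PanelError("empty distance matrix")
    if n == 1:
        warnings.warn("single taxon: trivial tree")
        return f"{_quote(labels[0])};"
    if n == 2:
        warnings.warn("two taxa: trivial tree")
        h = D[0, 1] / 2.0
        return f"({_quote(labels[0])}:{h:.17g},{_quote(labels[1])}:{h:.17g});"

    nodes = [_Node(lab) for lab in labels]
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, transferring the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    # final three nodes: trifurcating root, three-point branch lengths
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    lens = [li, lj, lk]
    for a in range(3):
        if lens[a] < 0:  # transfer the deficit to the longest sister branch
            b = int(np.argmax([lens[x] if x != a else -np.inf for x in range(3)]))
            lens[b] += lens[a]
            lens[a] = 0.0
    root = _Node(children=list(zip((nodes[i], nodes[j], nodes[k]), lens)))
    return _newick(root) + ";"
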