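"""Hierarchical clustering with multiscale-bootstrap support values.

Cells are clustered agglomeratively (average linkage by default) on either
the expression distance (1 - Spearman of log2(FPKM+1)) or the variant
distance (weighted genotype discordance). Cluster support is assessed by
multiscale bootstrap over *features* (genes or SNP sites; cells are never
resampled): at each scale r the features are resampled with replacement to
size round(r * n_features), the cells are re-clustered, and BP_r(node) is the
fraction of replicate trees containing the node's exact leaf set. The scale
dependence of BP is then converted into an approximately-unbiased (AU)
support probability by fitting

    probit(1 - BP_r) = v * sigma_r + c / sigma_r,   sigma_r = sqrt(1/r)

by weighted least squares (binomial delta-method weights) and reporting
AU = 100 * (1 - Phi(v - c)). An AU of at least 95 is read as cluster support
at p < 0.05.

Degenerate, perfectly separable data can hold BP at 0 or 1 at every scale;
the probit is then unbounded, so only scales with 0 < BP < 1 enter the fit,
and nodes degenerate at (almost) every scale short-circuit to AU = 100 when
BP sits at the ceiling and AU = 0 when it sits on the floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterTree:
    """Agglomerative merge tree over named leaves.

    Node ids: leaves are 0..n-1 in ``leaves`` order; the i-th merge creates
    internal node n+i, with the root at 2n-2. ``merges`` lists
    (left_child_id, right_child_id, height). Bootstrap annotations
    (``bp_by_scale``, ``au``, ``fit_diagnostics``) are present only after
    ``multiscale_bootstrap``.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]
    bp_by_scale: dict[int, dict[float, float]] = field(default_factory=dict)
    au: dict[int, float] = field(default_factory=dict)
    fit_diagnostics: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    n_imputed_distances: int = 0

    def __post_init__(self):
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ClusteringError("a binary merge tree needs n_leaves - 1 merges")
        self._leafsets: dict[int, frozenset[int]] = {
            i: frozenset([i]) for i in range(n)
        }
        for k, (a, b, _h) in enumerate(self.merges):
            self._leafsets[n + k] = self._leafsets[a] | self._leafsets[b]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root_id(self) -> int:
        return 2 * self.n_leaves - 2

    @property
    def internal_ids(self) -> list[int]:
        return list(range(self.n_leaves, 2 * self.n_leaves - 1))

    def leafset(self, node_id: int) -> frozenset[int]:
        return self._leafsets[node_id]

    def leaf_names(self, node_id: int) -> frozenset[str]:
        return frozenset(self.leaves[i] for i in self._leafsets[node_id])

    def height(self, node_id: int) -> float:
        n = self.n_leaves
        return 0.0 if node_id < n else self.merges[node_id - n][2]

    def children(self, node_id: int) -> tuple[int, int]:
        a, b, _ = self.merges[node_id - self.n_leaves]
        return a, b

    def node_table(self) -> pd.DataFrame:
        rows = []
        for nid in self.internal_ids:
            rows.append(
                {
                    "node_id": nid,
                    "leaves": ",".join(sorted(self.leaf_names(nid))),
                    "height": self.height(nid),
                    "au": self.au.get(nid, np.nan),
                    "bp_at_1": self.bp_by_scale.get(nid, {}).get(1.0, np.nan),
                }
            )
        return pd.DataFrame(rows)


def spearman_distance(X) -> np.ndarray:
    """1 - Spearman correlation between columns (cells) of a feature matrix.

    Zero-variance columns produce NaN entries, which downstream clustering
    imputes as the matrix maximum.
    """
    from scipy.stats import rankdata

    X = np.asarray(X, dtype=float)
    ranks = rankdata(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    return 1.0 - corr


def _agglomerate(dist: np.ndarray, linkage: str = "average") -> list[tuple[int, int, float]]:
    """Average/single/complete-linkage merge sequence via Lance-Williams.

    Ties are broken deterministically: among all minimal-distance pairs the
    lexicographically smallest pair of active-cluster positions (creation
    order) merges first.
    """
    if linkage not in ("average", "single", "complete"):
        raise ClusteringError(f"unsupported linkage {linkage!r}")
    D = np.array(dist, dtype=float)
    n = D.shape[0]
    np.fill_diagonal(D, np.inf)
    ids = list(range(n))
    sizes = [1] * n
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(ids) > 1:
        m = D.shape[0]
        iu = np.triu_indices(m, 1)
        k = int(np.argmin(D[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        h = float(D[i, j])
        ni, nj = sizes[i], sizes[j]
        if linkage == "average":
            row = (ni * D[i, :] + nj * D[j, :]) / (ni + nj)
        elif linkage == "single":
            row = np.minimum(D[i, :], D[j, :])
        else:
            row = np.maximum(D[i, :], D[j, :])
        merges.append((ids[i], ids[j], h))
        D[i, :] = row
        D[:, i] = row
        D[i, i] = np.inf
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        sizes[i] = ni + nj
        del sizes[j]
        ids[i] = next_id
        del ids[j]
        next_id += 1
    return merges


def _replicate_leafsets(merges: list[tuple[int, int, float]], n: int) -> set[frozenset[int]]:
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out: set[frozenset[int]] = set()
    for k, (a, b, _h) in enumerate(merges):
        s = sets[a] | sets[b]
        sets[n + k] = s
        out.add(s)
    return out


def _prepare_distance(distance_matrix, labels) -> tuple[np.ndarray, list[str], int]:
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        D = distance_matrix.values.astype(float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        if labels is None:
            labels = [f"leaf{i}" for i in range(D.shape[0])]
        labels = list(labels)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ClusteringError("distance matrix must be square")
    if D.shape[0] < 2:
        raise ClusteringError("clustering needs >= 2 leaves")
    finite = np.isfinite(D)
    sym_ok = np.allclose(D[finite & finite.T & np.isfinite(D.T)], D.T[finite & finite.T & np.isfinite(D.T)], atol=1e-9) if finite.any() else True
    if not sym_ok or not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ClusteringError("distance matrix must be symmetric with zero diagonal")
    D = np.array(D)
    np.fill_diagonal(D, 0.0)
    off_missing = ~np.isfinite(D)
    n_missing = int(off_missing.sum())
    if n_missing:
        if not np.isfinite(D).any():
            raise ClusteringError("all pairwise distances missing")
        mx = np.nanmax(np.where(np.isfinite(D), D, np.nan))
        logger.warning("imputing %d missing pairwise distances as matrix max %.4g", n_missing, mx)
        D[off_missing] = mx
    return D, labels, n_missing


def hierarchical_cluster(
    distance_matrix,
    labels: Sequence[str] | None = None,
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of a symmetric zero-diagonal distance matrix.

    Missing (NaN) pairwise distances are imputed as the matrix maximum and
    counted on the returned tree.
    """
    D, names, n_missing = _prepare_distance(distance_matrix, labels)
    merges = _agglomerate(D, linkage=linkage)
    return ClusterTree(leaves=names, merges=merges, n_imputed_distances=n_missing)


def multiscale_bootstrap(
    feature_matrix,
    distance_fn: Callable[[np.ndarray], np.ndarray],
    scales: Sequence[float] = DEFAULT_SCALES,
    B: int = 1000,
    seed: int = 0,
    labels: Sequence[str] | None = None,
    linkage: str = "average",
) -> ClusterTree:
    """Cluster cells and attach multiscale-bootstrap BP and AU values.

    ``feature_matrix`` is features (genes or SNP sites) x cells; columns are
    cells. ``distance_fn`` maps a resampled feature submatrix to a cells x
    cells distance matrix (NaNs allowed; imputed as matrix max). Deterministic
    given ``seed``.
    """
    if isinstance(feature_matrix, pd.DataFrame):
        labels = list(feature_matrix.columns)
        X = feature_matrix.values
    else:
        X = np.asarray(feature_matrix)
    n_features, n_cells = X.shape
    if n_features < 10:
        raise ClusteringError(f"multiscale bootstrap needs >= 10 features, got {n_features}")
    if B < 100:
        logger.warning("B = %d < 100; AU values will be unstable", B)
    if labels is None:
        labels = [f"cell{i}" for i in range(n_cells)]

    ref_D, names, n_missing = _prepare_distance(distance_fn(X), labels)
    tree = ClusterTree(
        leaves=names, merges=_agglomerate(ref_D, linkage=linkage),
        n_imputed_distances=n_missing,
    )
    targets = {tree.leafset(nid): nid for nid in tree.internal_ids}

    rng = np.random.default_rng(seed)
    scales = [float(r) for r in scales]
    bp: dict[int, dict[float, float]] = {nid: {} for nid in tree.internal_ids}
    for r in scales:
        m = max(1, int(round(r * n_features)))
        counts = {nid: 0 for nid in tree.internal_ids}
        for _ in range(B):
            idx = rng.integers(0, n_features, size=m)
            D = np.asarray(distance_fn(X[idx]), dtype=float)
            bad = ~np.isfinite(D)
            if bad.any():
                mx = np.nanmax(np.where(np.isfinite(D), D, np.nan))
                D[bad] = mx
                np.fill_diagonal(D, 0.0)
            for s in _replicate_leafsets(_agglomerate(D, linkage=linkage), n_cells):
                nid = targets.get(s)
                if nid is not None:
                    counts[nid] += 1
        for nid in tree.internal_ids:
            bp[nid][r] = counts[nid] / B

    tree.bp_by_scale = bp
    _fit_au(tree, scales, B)
    return tree


def _fit_au(tree: ClusterTree, scales: list[float], B: int) -> None:
    """Fit the signed-distance/curvature model per node and set AU values.

    The probit of a bootstrap proportion sitting at 0 or 1 is unbounded, so
    only scales with 0 < BP < 1 enter the weighted fit, and the two-parameter
    model needs at least three informative scales to be overdetermined. A
    node that is degenerate at nearly every scale is therefore decided by
    its mean BP: at the ceiling (cluster recovered in essentially every
    replicate at every scale) AU = 100; on the floor AU = 0.
    """
    for nid in tree.internal_ids:
        raw = np.array([tree.bp_by_scale[nid][r] for r in scales])
        usable = (raw > 0.0) & (raw < 1.0)
        if usable.sum() < 3:
            tree.au[nid] = 100.0 if raw.mean() >= 0.5 else 0.0
            tree.fit_diagnostics[nid] = (float("nan"), float("nan"), 0.0)
            continue
        bp = raw[usable]
        z = norm.ppf(1.0 - bp)
        sigma = np.sqrt(1.0 / np.asarray(scales)[usable])
        # binomial delta-method weights: Var(z) ~ bp(1-bp) / (B phi(z)^2)
        w = B * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
        A = np.column_stack([sigma, 1.0 / sigma])
        WA = A * w[:, None]
        beta, *_ = np.linalg.lstsq(WA.T @ A, WA.T @ z, rcond=None)
        v, c = float(beta[0]), float(beta[1])
        resid = float(np.sum(w * (z - A @ beta) ** 2))
        tree.au[nid] = float(100.0 * (1.0 - norm.cdf(v - c)))
        tree.fit_diagnostics[nid] = (v, c, resid)


def significant_clusters(tree: ClusterTree, alpha: float = 0.05) -> list[frozenset[str]]:
    """Maximal non-root internal nodes with AU >= 100 * (1 - alpha)."""
    if not tree.au:
        raise ClusteringError("AU values not computed; run multiscale_bootstrap first")
    cutoff = 100.0 * (1.0 - alpha)
    hits = [
        nid for nid in tree.internal_ids
        if nid != tree.root_id and tree.au.get(nid, 0.0) >= cutoff
    ]
    maximal = []
    for nid in hits:
        s = tree.leafset(nid)
        if not any(s < tree.leafset(other) for other in hits if other != nid):
            maximal.append(nid)
    return [tree.leaf_names(nid) for nid in maximal]


def to_newick(tree: ClusterTree, au_labels: bool = True, decimals: int = 6) -> str:
    """Newick text with merge-height branch lengths and AU internal labels."""
    def fmt(x: float) -> str:
        return f"{x:.{decimals}g}"

    def render(nid: int, parent_height: float) -> str:
        bl = fmt(max(parent_height - tree.height(nid), 0.0))
        if nid < tree.n_leaves:
            return f"{tree.leaves[nid]}:{bl}"
        a, b = tree.children(nid)
        h = tree.height(nid)
        inner = f"({render(a, h)},{render(b, h)})"
        label = ""
        if au_labels and nid in tree.au:
            label = f"{tree.au[nid]:.0f}"
        return f"{inner}{label}:{bl}"

    root = tree.root_id
    a, b = tree.children(root)
    h = tree.height(root)
    label = f"{tree.au[root]:.0f}" if (au_labels and root in tree.au) else ""
    return f"({render(a, h)},{render(b, h)}){label};"
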