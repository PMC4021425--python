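"""Strategy-comparison analytics on the clade-count matrix S.

Covers clade-size/balance statistics, PCA of clade counts, classical MDS of
mean Robinson-Foulds distances between bootstrap tree sets, Procrustes
influence of strategy subsets, Ward and K-means clustering, nonzero-restricted
Pearson correlation, clade flow, and representative greedy-consensus
topologies with averaged supports.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import orthogonal_procrustes
from sklearn.cluster import KMeans

from .bootstrap import CladeCountMatrix, StrategyDescriptor
from .speciestree import greedy_consensus
from .trees import clade_masks, leaf_labels, rf_between_masks

log = logging.getLogger("treestrat")

__all__ = [
    "clade_size_stats",
    "robinson_foulds",
    "mean_rf_matrix",
    "EmbeddingCoordinates",
    "pca_embed",
    "mds_embed",
    "ProcrustesFit",
    "procrustes_dissimilarity",
    "procrustes_influence",
    "ClusteringResult",
    "ward_dendrogram",
    "kmeans_cluster",
    "nonzero_correlation",
    "clade_flow",
    "representative_topology",
]


# ---------------------------------------------------------------------------
# clade size / balance


def clade_size_stats(
    clade_counts: Mapping[int, float]
) -> Tuple[np.ndarray, float, float]:
    """(cumulative size distribution, mean clade size, standard error).

    Clade *instances* are weighted by their counts; the cumulative
    distribution is indexed by size starting at 2.
    """
    if not clade_counts:
        raise ValueError("no clades")
    sizes = np.array([bin(m).count("1") for m in clade_counts], dtype=float)
    weights = np.array(list(clade_counts.values()), dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no clade instances")
    mean = float((sizes * weights).sum() / total)
    var = float((weights * (sizes - mean) ** 2).sum() / total)
    se = float(np.sqrt(var / total))
    max_size = int(sizes.max())
    cdf = np.zeros(max_size - 1)
    for s, w in zip(sizes, weights):
        cdf[int(s) - 2] += w
    cdf = np.cumsum(cdf) / total
    return cdf, mean, se


# ---------------------------------------------------------------------------
# Robinson-Foulds distances


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Rooted RF distance: size of the symmetric difference of the
    non-trivial clade sets."""
    from .trees import robinson_foulds as _rf
    return _rf(t1, t2)


def mean_rf_matrix(
    tree_sets: Sequence[Sequence[dendropy.Tree]],
    pair_budget: int = 1_000_000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Strategy x strategy mean RF over all BxB cross pairs of bootstrap
    trees; pairs are subsampled (seeded) when B^2 exceeds ``pair_budget``."""
    n = len(tree_sets)
    mask_sets: List[List[frozenset]] = []
    for ts in tree_sets:
        if not ts:
            raise ValueError("empty tree set")
        labels = sorted(leaf_labels(ts[0]))
        mask_sets.append([clade_masks(t, labels) for t in ts])
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mask_sets[i], mask_sets[j]
            npairs = len(a) * len(b)
            if npairs <= pair_budget:
                tot = sum(rf_between_masks(x, y) for x in a for y in b)
                mean = tot / npairs
            else:
                if rng is None:
                    raise ValueError("pair budget exceeded but no rng given")
                log.info("mean_rf_matrix: subsampling %d of %d pairs",
                         pair_budget, npairs)
                ii = rng.integers(len(a), size=pair_budget)
                jj = rng.integers(len(b), size=pair_budget)
                mean = float(
                    np.mean([rf_between_masks(a[x], b[y]) for x, y in zip(ii, jj)])
                )
            out[i, j] = out[j, i] = mean
    return out


# ---------------------------------------------------------------------------
# embeddings


@dataclass
class EmbeddingCoordinates:
    """2-D strategy map with per-component variance fractions."""

    coords: np.ndarray  # (n, 2)
    variance_fractions: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")


def pca_embed(S: CladeCountMatrix | np.ndarray) -> EmbeddingCoordinates:
    """Top-2 principal components of the clade-count matrix.

    Columns are centered but not variance-scaled (counts share the 0..B
    scale); components come from the singular decomposition.
    """
    X = S.values if isinstance(S, CladeCountMatrix) else np.asarray(S, dtype=float)
    X = X.astype(float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs >= 3 strategies")
    Xc = X - X.mean(axis=0)
    total = (Xc ** 2).sum()
    if total <= 0:
        log.warning("constant matrix: degenerate PCA, zero coordinates")
        return EmbeddingCoordinates(np.zeros((X.shape[0], 2)), np.zeros(2))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :2] * s[:2]
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((X.shape[0], 1))])
        s = np.append(s, 0.0)
    fractions = (s[:2] ** 2) / total
    return EmbeddingCoordinates(coords, fractions)


def mds_embed(distances: np.ndarray) -> EmbeddingCoordinates:
    """Classical (principal-coordinate) scaling: double-center the squared
    distances and take the top-2 eigenvectors."""
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("need a square matrix")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(Bmat)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = np.clip(w, 0.0, None)
    coords = V[:, :2] * np.sqrt(pos[:2])[None, :]
    total = pos.sum()
    fractions = pos[:2] / total if total > 0 else np.zeros(2)
    return EmbeddingCoordinates(coords, fractions)


# ---------------------------------------------------------------------------
# Procrustes


@dataclass
class ProcrustesFit:
    """Least-squares similarity superimposition of Y onto X.

    ``fitted = scale * Y @ transform + translation``; the dissimilarity is
    the residual sum of squares divided by the centered scatter of X, and
    lies in [0, 1] (a zero-scale fit bounds the numerator by the
    denominator).
    """

    target: np.ndarray
    comparison: np.ndarray
    scale: float
    transform: np.ndarray  # 2x2 orthogonal (reflections allowed)
    translation: np.ndarray
    fitted: np.ndarray
    dissimilarity: float
    centroid: np.ndarray

    def __post_init__(self) -> None:
        T = self.transform
        if not np.allclose(T.T @ T, np.eye(T.shape[0]), atol=1e-10):
            raise ValueError("transform is not orthogonal")


def procrustes_dissimilarity(X: np.ndarray, Y: np.ndarray) -> ProcrustesFit:
    """Optimal scaling b, orthogonal T (rotation/reflection) and translation
    C minimizing ||X - (b Y T + C)||^2, with the normalized residual."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("X and Y must have the same 2-D shape")
    mu_x = X.mean(axis=0)
    mu_y = Y.mean(axis=0)
    Xc = X - mu_x
    Yc = Y - mu_y
    denom = (Xc ** 2).sum()
    if denom <= 0:
        raise ValueError("target has zero scatter; dissimilarity undefined")
    ynorm2 = (Yc ** 2).sum()
    if ynorm2 <= 0:
        T = np.eye(X.shape[1])
        b = 0.0
    else:
        T, s = orthogonal_procrustes(Yc, Xc)  # allows reflection
        b = s / ynorm2
    C = mu_x - b * mu_y @ T
    Z = b * Y @ T + C
    diss = float(((X - Z) ** 2).sum() / denom)
    return ProcrustesFit(X, Y, float(b), T, C, Z, diss, mu_x)


def procrustes_influence(
    S: CladeCountMatrix | np.ndarray, removed: Sequence[int]
) -> float:
    """Influence of a strategy subset: Procrustes dissimilarity between the
    full-matrix PCA coordinates restricted to the retained strategies and the
    PCA of the retained submatrix."""
    X = S.values if isinstance(S, CladeCountMatrix) else np.asarray(S, dtype=float)
    keep = np.array([i for i in range(X.shape[0]) if i not in set(removed)])
    if len(keep) < 3:
        raise ValueError("need >= 3 retained strategies")
    full = pca_embed(X).coords[keep]
    sub = pca_embed(X[keep]).coords
    return procrustes_dissimilarity(full, sub).dissimilarity


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusteringResult:
    method: str  # ward | kmeans
    labels: np.ndarray  # 1..K
    K: int
    merge_history: Optional[np.ndarray] = None  # scipy linkage matrix (ward)
    wss: Optional[float] = None  # total within-cluster sum of squares (kmeans)


def ward_dendrogram(S: CladeCountMatrix | np.ndarray, K: int = 2) -> ClusteringResult:
    """Ward minimum-variance agglomeration on Euclidean distances between
    strategy rows; the full merge history is retained and labels are cut at
    K clusters."""
    X = S.values if isinstance(S, CladeCountMatrix) else np.asarray(S, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 strategies")
    Z = linkage(X.astype(float), method="ward")
    labels = fcluster(Z, t=K, criterion="maxclust")
    return ClusteringResult("ward", labels, K, merge_history=Z)


def _wss_of(X: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for k in np.unique(labels):
        pts = X[labels == k]
        tot += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(tot)


def kmeans_cluster(
    S: CladeCountMatrix | np.ndarray,
    K: int,
    restarts: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> ClusteringResult:
    """Lloyd K-means, best of ``restarts`` random starts; additionally the
    best (K-1)-cluster solution (when K > 2) seeds one extra restart by
    splitting its widest cluster, enforcing WSS(K) <= WSS(K-1)."""
    X = S.values if isinstance(S, CladeCountMatrix) else np.asarray(S, dtype=float)
    X = X.astype(float)
    n = X.shape[0]
    if not 2 <= K <= n:
        raise ValueError("need 2 <= K <= number of strategies")
    if rng is None:
        rng = np.random.default_rng(0)
    seed = int(rng.integers(2 ** 31 - 1))
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    best_labels, best_wss = labels, _wss_of(X, labels)
    if K > 2:
        prev = kmeans_cluster(X, K - 1, restarts=restarts,
                              rng=np.random.default_rng(seed))
        centers = []
        for k in np.unique(prev.labels):
            centers.append(X[prev.labels == k].mean(axis=0))
        # split the cluster with the largest internal scatter at its farthest point
        scatters = [
            ((X[prev.labels == k] - c) ** 2).sum()
            for k, c in zip(np.unique(prev.labels), centers)
        ]
        widest = np.unique(prev.labels)[int(np.argmax(scatters))]
        pts = X[prev.labels == widest]
        far = pts[np.argmax(((pts - pts.mean(axis=0)) ** 2).sum(axis=1))]
        init = np.vstack(centers + [far])
        km2 = KMeans(n_clusters=K, n_init=1, init=init, algorithm="lloyd")
        labels2 = km2.fit_predict(X)
        wss2 = _wss_of(X, labels2)
        if wss2 < best_wss:
            best_labels, best_wss = labels2, wss2
    return ClusteringResult("kmeans", best_labels + 1, K, wss=best_wss)


# ---------------------------------------------------------------------------
# correlations, clade flow, representative topologies


def nonzero_correlation(
    S: CladeCountMatrix | np.ndarray, i: int, j: int
) -> float:
    """Pearson correlation between two strategy rows over the clades nonzero
    in both."""
    X = S.values if isinstance(S, CladeCountMatrix) else np.asarray(S, dtype=float)
    a, b = X[i].astype(float), X[j].astype(float)
    mask = (a != 0) & (b != 0)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 shared nonzero clades")
    aa, bb = a[mask], b[mask]
    if aa.std() == 0 or bb.std() == 0:
        return 1.0 if np.allclose(aa / aa.sum(), bb / bb.sum()) else 0.0
    return float(np.corrcoef(aa, bb)[0, 1])


def clade_flow(
    S: CladeCountMatrix | np.ndarray, weighted: bool = True
) -> np.ndarray:
    """Entry (i, j): fraction of strategy i's inferred clades absent from
    strategy j's observed clade set.

    ``weighted`` counts clade instances (each of the sum_c S_ic bootstrap
    occurrences); unweighted counts distinct clades.  Asymmetric; diagonal 0.
    """
    X = S.values if isinstance(S, CladeCountMatrix) else np.asarray(S, dtype=float)
    X = X.astype(float)
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        support = X[i] if weighted else (X[i] > 0).astype(float)
        tot = support.sum()
        if tot == 0:
            out[i] = np.nan
            log.warning("clade_flow: strategy %d has no inferred clades", i)
            continue
        for j in range(n):
            if i == j:
                continue
            out[i, j] = support[X[j] == 0].sum() / tot
    return out


def representative_topology(
    S: CladeCountMatrix, rows: Sequence[int]
) -> dendropy.Tree:
    """Greedy consensus of the clade counts averaged (arithmetic mean) over a
    strategy subset; accepted clades are annotated with their averaged
    counts."""
    if not rows:
        raise ValueError("empty strategy subset")
    mean_counts = S.values[list(rows)].mean(axis=0)
    counts = {
        mask: float(c) for mask, c in zip(S.clades, mean_counts) if c > 0
    }
    return greedy_consensus(counts, S.labels)
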