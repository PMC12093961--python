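"""Autofluorescence shape classification: PCA, X-means, hierarchical.

The emission *shape* (not intensity) distinguishes pigment families —
bacteriochlorophyll-a-like spectra rise again past ~740 nm while
bacteriochlorophyll-b-like spectra do not — so each cell's autofluorescence
component is truncated to 665-775 nm (dropping fit divergence at the axis
ends), min-max rescaled to [0, 1], embedded with PCA, and clustered with
X-means, which grows the cluster count by accepting BIC-improving k=2 splits
instead of requiring k up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .quantification import AF_SHAPE_WINDOW_NM
from .spectra_io import Spectrum

__all__ = [
    "PcaResult",
    "ClusterResult",
    "prepare_af_matrix",
    "pca",
    "xmeans",
    "hcluster",
    "classify_af_shapes",
]


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    k: int
    centroids: np.ndarray
    params: dict = field(default_factory=dict)
    pc_scores: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None


def prepare_af_matrix(
    af_spectra: list[Spectrum],
    window_nm: tuple[float, float] = AF_SHAPE_WINDOW_NM,
) -> tuple[np.ndarray, list[int], list[dict]]:
    """Truncate AF spectra to a wavelength window and min-max normalize rows.

    Returns (matrix, kept indices, rejection log); constant rows (max == min)
    cannot be rescaled and are rejected.
    """
    if not af_spectra:
        raise ValueError("no spectra")
    idx = af_spectra[0].axis.index_window_nm(*window_nm)
    if idx.size < 2:
        raise ValueError(f"window {window_nm} nm outside axis")
    rows, kept, log = [], [], []
    for i, s in enumerate(af_spectra):
        seg = s.intensities[s.axis.index_window_nm(*window_nm)]
        lo, hi = float(np.min(seg)), float(np.max(seg))
        if hi == lo:
            log.append({"index": i, "cell_id": s.cell_id, "reason": "constant spectrum"})
            continue
        rows.append((seg - lo) / (hi - lo))
        kept.append(i)
    return np.asarray(rows), kept, log


def pca(matrix: np.ndarray, n_components: int = 7) -> PcaResult:
    """Mean-centered PCA (no variance scaling; rows are already min-max scaled)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    max_comp = min(matrix.shape[0], matrix.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} clipped to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix)
    return PcaResult(
        scores=scores,
        loadings=model.components_,
        explained_variance_ratio=model.explained_variance_ratio_,
        mean=model.mean_,
    )


def _bic(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """BIC splitting score of a spherical-Gaussian k-means model.

    Pelleg-Moore likelihood with the parameter penalty charged per cluster
    (the convention of the clustering library this stage reproduces); the
    per-cluster penalty is deliberately conservative, which keeps X-means
    from shattering elongated but single clusters.
    """
    n, d = points.shape
    k = centroids.shape[0]
    if n <= k:
        return -np.inf
    sq = 0.0
    counts = np.zeros(k)
    for j in range(k):
        mask = labels == j
        counts[j] = mask.sum()
        if counts[j]:
            sq += float(np.sum((points[mask] - centroids[j]) ** 2))
    sigma2 = sq / (n - k)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    n_params = (k - 1) + k * d + 1
    score = 0.0
    for j in range(k):
        nj = counts[j]
        if nj == 0:
            continue
        ll_j = (
            nj * np.log(nj)
            - nj * np.log(n)
            - nj * 0.5 * np.log(2.0 * np.pi)
            - nj * d * 0.5 * np.log(sigma2)
            - (nj - k) * 0.5
        )
        score += ll_j - n_params * 0.5 * np.log(n)
    return float(score)


def _kmeans(points, k, seed, tol):
    km = KMeans(n_clusters=k, n_init=10, tol=tol, random_state=seed)
    labels = km.fit_predict(points)
    return labels, km.cluster_centers_


def xmeans(
    scores: np.ndarray,
    k_init: int = 2,
    k_max: int = 20,
    tolerance: float = 1e-4,
    seed: int = 0,
    min_cluster_size: int = 2,
) -> ClusterResult:
    """X-means: k-means plus BIC-scored cluster splitting.

    Starting from ``k_init`` centroids, every cluster is tentatively split in
    two; a split is kept when the two-cluster BIC of that cluster's points
    exceeds the one-cluster BIC.  Rounds of global k-means refinement and
    splitting alternate until no split is accepted or ``k_max`` is reached.
    Deterministic for a given seed.  Clusters smaller than
    ``2 * min_cluster_size`` are never split.
    """
    points = np.asarray(scores, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if k_init > n:
        raise ValueError(f"k_init={k_init} exceeds {n} observations")
    k_max = min(k_max, n)
    rng = np.random.default_rng(seed)
    labels, centroids = _kmeans(points, k_init, int(rng.integers(2**31)), tolerance)
    k = k_init
    while k < k_max:
        new_centroids = []
        split_any = False
        for j in range(centroids.shape[0]):
            mask = labels == j
            sub = points[mask]
            if k + 1 > k_max or sub.shape[0] < max(2 * min_cluster_size, 4):
                new_centroids.append(centroids[j])
                continue
            parent_bic = _bic(sub, np.zeros(sub.shape[0], dtype=int),
                              sub.mean(axis=0, keepdims=True))
            sub_labels, sub_centroids = _kmeans(
                sub, 2, int(rng.integers(2**31)), tolerance
            )
            sizes = np.bincount(sub_labels, minlength=2)
            child_bic = _bic(sub, sub_labels, sub_centroids)
            if child_bic > parent_bic and np.all(sizes >= min_cluster_size):
                new_centroids.extend(sub_centroids)
                split_any = True
                k += 1
            else:
                new_centroids.append(centroids[j])
        if not split_any:
            break
        # global refinement from the accepted centroid set
        km = KMeans(
            n_clusters=len(new_centroids),
            init=np.asarray(new_centroids),
            n_init=1,
            tol=tolerance,
        )
        labels = km.fit_predict(points)
        centroids = km.cluster_centers_
        k = centroids.shape[0]
    return ClusterResult(
        labels=labels,
        k=int(centroids.shape[0]),
        centroids=centroids,
        params={
            "k_init": k_init,
            "k_max": k_max,
            "tolerance": tolerance,
            "seed": seed,
            "min_cluster_size": min_cluster_size,
        },
    )


def hcluster(
    matrix: np.ndarray,
    method: str = "ward",
    metric: str = "euclidean",
    n_clusters: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Agglomerative clustering; returns (linkage matrix, cut labels or None)."""
    valid_methods = {"single", "complete", "average", "weighted", "centroid",
                     "median", "ward"}
    if method not in valid_methods:
        raise ValueError(f"unknown linkage method {method!r}")
    try:
        Z = scipy_linkage(np.asarray(matrix, dtype=float), method=method, metric=metric)
    except ValueError as exc:
        raise ValueError(f"invalid metric {metric!r} for linkage {method!r}: {exc}")
    labels = None
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return Z, labels


def classify_af_shapes(
    af_spectra: list[Spectrum],
    window_nm: tuple[float, float] = AF_SHAPE_WINDOW_NM,
    n_components: int = 7,
    k_init: int = 2,
    k_max: int = 20,
    tolerance: float = 1e-4,
    seed: int = 0,
) -> tuple[ClusterResult, list[int], list[dict]]:
    """prepare -> PCA -> X-means, the AF shape-classification pipeline stage."""
    matrix, kept, log = prepare_af_matrix(af_spectra, window_nm)
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 usable AF spectra for clustering")
    p = pca(matrix, n_components=n_components)
    res = xmeans(p.scores, k_init=k_init, k_max=k_max, tolerance=tolerance, seed=seed)
    res = ClusterResult(
        labels=res.labels,
        k=res.k,
        centroids=res.centroids,
        params=res.params,
        pc_scores=p.scores,
        explained_variance_ratio=p.explained_variance_ratio,
    )
    return res, kept, log
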