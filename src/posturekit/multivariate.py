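"""Dimensionality reduction and cluster discovery over postural profiles.

PCA (covariance by default: the profile mixes pixel-length vectors with
small angles, and the length structure is what the cluster layer looks for;
a z-score mode is available), component selection by cumulative explained
variance, five clustering algorithms (k-means, mean-shift, Ward, complete
and average linkage), elbow and silhouette model selection, and the
cluster-stratified re-analysis of the profile table.

Clustering operates in the retained principal-component score space by
default; mean-shift estimates its bandwidth from the data with the 0.3
nearest-neighbour quantile rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans, MeanShift, estimate_bandwidth
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import InsufficientSampleError, InvalidInputError
from .geometry import PARAMETER_NAMES
from .stats import compare_groups

CLUSTER_METHODS = ("kmeans", "meanshift", "ward", "complete", "average")
DEFAULT_SEED = 20230315
DEFAULT_BANDWIDTH_QUANTILE = 0.3


@dataclass
class PCAResult:
    """Principal component decomposition of a subjects x parameters matrix."""

    loadings: np.ndarray  # (n_parameters, n_components), orthonormal columns
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_subjects, n_components)
    scaling: str  # "none" | "zscore"
    mean_: np.ndarray
    scale_: np.ndarray

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        """Back-project scores to the original parameter space."""
        m = self.loadings.shape[1] if n_components is None else n_components
        x = self.scores[:, :m] @ self.loadings[:, :m].T
        return x * self.scale_ + self.mean_


def run_pca(matrix, scaling: str = "none") -> PCAResult:
    """PCA of a subjects x parameters matrix.

    ``scaling="none"`` decomposes the covariance structure, ``"zscore"`` the
    correlation structure.  Loadings follow a deterministic sign convention:
    the largest-magnitude loading of each component is positive.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("matrix must be 2-D (subjects x parameters)")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("missing values in the profile matrix")
    if scaling not in ("none", "zscore"):
        raise InvalidInputError(f"unknown scaling {scaling!r}")
    mean = x.mean(axis=0)
    if scaling == "zscore":
        scale = x.std(axis=0, ddof=1)
        if np.any(scale == 0.0):
            raise InvalidInputError("zero-variance column under zscore scaling")
    else:
        scale = np.ones(x.shape[1])
    xs = (x - mean) / scale
    pca = PCA()
    scores = pca.fit_transform(xs)
    loadings = pca.components_.T.copy()
    # sign convention: flip components whose extreme loading is negative
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=scores,
        scaling=scaling,
        mean_=mean,
        scale_=scale,
    )


def select_components(result: PCAResult | np.ndarray, retention: float = 0.90) -> int:
    """Smallest component count whose cumulative variance ratio reaches
    ``retention``; accepts a PCAResult or a ratio sequence."""
    if not 0.0 < retention <= 1.0:
        raise InvalidInputError("retention must be in (0, 1]")
    ratios = (
        result.explained_variance_ratio
        if isinstance(result, PCAResult)
        else np.asarray(result, dtype=float)
    )
    cum = np.cumsum(ratios)
    hits = np.nonzero(cum >= retention - 1e-12)[0]
    return int(hits[0]) + 1 if hits.size else int(ratios.size)


@dataclass
class ClusterResult:
    method: str
    labels: np.ndarray
    n_clusters: int
    silhouette: float | None
    params: dict


def silhouette(scores, labels) -> float:
    """Mean silhouette (b - a)/max(a, b) with Euclidean distances.

    Singleton clusters score 0; requires at least 2 clusters.
    """
    labels = np.asarray(labels)
    n_labels = np.unique(labels).size
    if n_labels < 2:
        raise InvalidInputError("silhouette undefined for a single cluster")
    if n_labels == labels.size:
        return 0.0  # all clusters are singletons; each point scores 0
    return float(silhouette_score(np.asarray(scores, dtype=float), labels))


def cluster(
    scores,
    method: str,
    n_clusters: int = 2,
    seed: int = DEFAULT_SEED,
    bandwidth: float | None = None,
    bandwidth_quantile: float = DEFAULT_BANDWIDTH_QUANTILE,
) -> ClusterResult:
    """Cluster PC scores with one of the five supported algorithms.

    k-means uses seeded greedy (k-means++) multi-restart; mean-shift
    estimates its bandwidth from the data unless one is given; the
    hierarchical methods cut the tree at ``n_clusters``.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 3:
        raise InsufficientSampleError("clustering needs at least 3 points")
    params: dict = {}
    if method == "kmeans":
        if n_clusters > n:
            raise InsufficientSampleError(f"k={n_clusters} infeasible with n={n} points")
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(x)
        params = {"k": n_clusters, "seed": seed, "inertia": float(km.inertia_)}
    elif method == "meanshift":
        bw = bandwidth
        if bw is None:
            bw = float(estimate_bandwidth(x, quantile=bandwidth_quantile, random_state=seed))
        if bw <= 0.0:  # all points (nearly) identical
            labels = np.zeros(n, dtype=int)
            params = {"bandwidth": 0.0}
        else:
            # seeds come from bandwidth-sized bins holding >= 2 points, so
            # an isolated subject cannot found a degenerate one-point mode;
            # stragglers are assigned to the nearest real mode
            try:
                ms = MeanShift(bandwidth=bw, bin_seeding=True, min_bin_freq=2, cluster_all=True)
                labels = ms.fit_predict(x)
            except ValueError:  # no bin reached the occupancy floor
                ms = MeanShift(bandwidth=bw)
                labels = ms.fit_predict(x)
            params = {"bandwidth": bw}
    elif method in ("ward", "complete", "average"):
        if n_clusters > n:
            raise InsufficientSampleError(f"k={n_clusters} infeasible with n={n} points")
        agg = AgglomerativeClustering(n_clusters=n_clusters, linkage=method)
        labels = agg.fit_predict(x)
        params = {"k": n_clusters}
    else:
        raise InvalidInputError(f"unknown clustering method {method!r}")
    labels = np.asarray(labels, dtype=int)
    k_found = int(np.unique(labels).size)
    sil = silhouette(x, labels) if k_found >= 2 else None
    return ClusterResult(
        method=method, labels=labels, n_clusters=k_found, silhouette=sil, params=params
    )


@dataclass
class ElbowCurve:
    ks: list[int]
    wcss: list[float]
    knee: int
    low_confidence: bool


def elbow_curve(scores, k_range=range(1, 9), seed: int = DEFAULT_SEED) -> ElbowCurve:
    """Within-cluster sum of squares over k (multi-restart k-means) with the
    knee located at the maximum second difference.

    The knee is flagged low-confidence when the curvature at the knee is
    small relative to the total WCSS drop (a shallow, featureless curve).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    ks = [int(k) for k in k_range]
    if not ks or ks[0] < 1 or ks[-1] >= x.shape[0] + 1:
        raise InvalidInputError("k_range must lie within [1, n]")
    wcss = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(x)
        wcss.append(float(km.inertia_))
    if len(ks) < 3:
        return ElbowCurve(ks, wcss, ks[-1], True)
    second = [wcss[i - 1] - 2 * wcss[i] + wcss[i + 1] for i in range(1, len(ks) - 1)]
    knee_idx = int(np.argmax(second)) + 1
    # shallow curve: no pronounced curvature anywhere (a featureless
    # 1/k-like decay), so the knee location carries little evidence
    low_conf = wcss[0] <= 0 or second[knee_idx - 1] < 0.2 * wcss[0]
    return ElbowCurve(ks, wcss, ks[knee_idx], low_conf)


def cluster_stratified_comparison(profile_frame, labels, welch: bool = False):
    """Per-parameter two-group comparison between the two discovered
    clusters, oriented so CG1 is the cluster with the smaller mean
    shoulder-hip difference (d signed as CG2 - CG1).

    Returns (comparisons, oriented_labels) where oriented labels are the
    strings "CG1"/"CG2".
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise InvalidInputError(f"expected exactly 2 clusters, got {uniq.size}")
    counts = [(labels == u).sum() for u in uniq]
    if min(counts) < 3:
        raise InsufficientSampleError("a cluster has fewer than 3 subjects")
    shd = np.asarray(profile_frame["shoulder_hip_difference"], dtype=float)
    means = [np.nanmean(shd[labels == u]) for u in uniq]
    cg1 = uniq[int(np.argmin(means))]
    named = np.where(labels == cg1, "CG1", "CG2")
    comparisons = []
    for param in PARAMETER_NAMES:
        if param not in profile_frame:
            continue
        vals = np.asarray(profile_frame[param], dtype=float)
        keep = np.isfinite(vals)
        a = vals[keep & (named == "CG1")]
        b = vals[keep & (named == "CG2")]
        if a.size < 3 or b.size < 3:
            continue
        comparisons.append(
            compare_groups(a, b, parameter=param, groups=("CG1", "CG2"), welch=welch)
        )
    return comparisons, named
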