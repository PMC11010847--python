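"""Scene preprocessing: voxel down-sampling and K-means segmentation.

Raw back-view captures are dense (hundreds of thousands of points) and
contain the pen floor and fence/wall structures besides the animal. Two
steps turn them into a pig-only cloud:

1. **Voxel filtering** — space is partitioned into cubic cells of side
   ``edgelength``; each occupied cell's points are replaced by their mean.
   This denoises and equalizes point density.
2. **K-means segmentation** — Lloyd's algorithm on xyz coordinates splits
   the scene into K compact clusters (pig, floor, fences); the number of
   clusters is chosen by the elbow of the SSE-vs-K curve, and the pig is the
   cluster closest to the overhead camera.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .pc_io import PointCloud

__all__ = [
    "VoxelFilterParams",
    "SegmentationResult",
    "voxel_downsample",
    "kmeans_cluster",
    "elbow_select_k",
    "extract_pig_cluster",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class VoxelFilterParams:
    """Cubic voxel grid parameters; ``edgelength`` is the cell side in m."""

    edgelength: float = 0.03

    def __post_init__(self):
        if not self.edgelength > 0:
            raise ValueError(f"edgelength must be > 0, got {self.edgelength}")


@dataclass
class SegmentationResult:
    """K-means output: per-point labels, cluster centroids and final SSE."""

    labels: np.ndarray          # (N,) ints in [0, K)
    centroids: np.ndarray       # (K, 3) meters
    K: int
    sse: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.shape != (self.K, 3):
            raise ValueError("centroids must be (K, 3)")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.K):
            raise ValueError("labels out of range [0, K)")
        counts = np.bincount(self.labels, minlength=self.K)
        if np.any(counts == 0):
            raise ValueError("every cluster must be non-empty")


def voxel_downsample(cloud: PointCloud, params: VoxelFilterParams) -> PointCloud:
    """Down-sample by averaging points within cubic voxels.

    The grid is anchored at the cloud's minimum corner with half-open cells
    ``[k*e, (k+1)*e)``. The output holds one point per occupied voxel at the
    arithmetic mean of its members; colors, when present, are the rounded
    per-voxel mean.
    """
    if len(cloud) == 0:
        raise ValueError("cannot voxel-downsample an empty cloud")
    e = params.edgelength
    origin = cloud.points.min(axis=0)
    idx = np.floor((cloud.points - origin) / e).astype(np.int64)
    _, inverse, counts = np.unique(
        idx, axis=0, return_inverse=True, return_counts=True
    )
    n_vox = len(counts)
    sums = np.zeros((n_vox, 3))
    np.add.at(sums, inverse, cloud.points)
    means = sums / counts[:, None]
    colors = None
    if cloud.has_colors:
        csums = np.zeros((n_vox, 3))
        np.add.at(csums, inverse, cloud.colors.astype(np.float64))
        colors = np.clip(np.rint(csums / counts[:, None]), 0, 255).astype(np.int64)
    return PointCloud(means, colors, source_id=cloud.source_id)


def _lloyd(points: np.ndarray, init: np.ndarray, tol: float, max_iter: int):
    """One Lloyd run from given initial centroids. Returns (labels, centroids, sse)."""
    centroids = init.copy()
    labels = np.zeros(len(points), dtype=np.int64)
    for _ in range(max_iter):
        d2 = cdist(points, centroids, "sqeuclidean")
        labels = np.argmin(d2, axis=1)
        new = np.empty_like(centroids)
        for j in range(len(centroids)):
            members = points[labels == j]
            if len(members) == 0:
                # empty-cluster repair: reseed from the point farthest
                # from its current centroid
                far = np.argmax(d2[np.arange(len(points)), labels])
                new[j] = points[far]
                labels[far] = j
            else:
                new[j] = members.mean(axis=0)
        shift = np.linalg.norm(new - centroids, axis=1).max()
        centroids = new
        if shift <= tol:
            break
    d2 = cdist(points, centroids, "sqeuclidean")
    labels = np.argmin(d2, axis=1)
    sse = float(d2[np.arange(len(points)), labels].sum())
    return labels, centroids, sse


def kmeans_cluster(
    cloud: PointCloud,
    K: int,
    seed: int = 0,
    n_restarts: int = 40,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> SegmentationResult:
    """Lloyd K-means on xyz coordinates, best of ``n_restarts`` by SSE.

    Centroids are initialized by uniform random choice of K distinct data
    points; iterations stop when no centroid moves more than ``tol`` meters.
    On scene-scale inputs the SSE landscape has a deep object-aligned
    optimum that sparse restarts can miss, hence the generous default.
    Deterministic for a fixed seed. RGB never enters the distance metric.
    """
    n = len(cloud)
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of points ({n})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        init = cloud.points[rng.choice(n, size=K, replace=False)]
        labels, centroids, sse = _lloyd(cloud.points, init, tol, max_iter)
        if best is None or sse < best[2]:
            best = (labels, centroids, sse)
    labels, centroids, sse = best
    # drop empty clusters (possible when distinct points < K effective)
    occupied = np.unique(labels)
    if len(occupied) < K:
        remap = -np.ones(K, dtype=np.int64)
        remap[occupied] = np.arange(len(occupied))
        labels = remap[labels]
        centroids = centroids[occupied]
        K = len(occupied)
    return SegmentationResult(labels, centroids, K, sse)


def elbow_select_k(
    cloud: PointCloud,
    k_range: tuple[int, int] = (1, 8),
    seed: int = 0,
    n_restarts: int = 40,
) -> tuple[int, np.ndarray]:
    """Choose K at the sharpest bend of the SSE(K) curve.

    SSE(K) is computed for every K in the inclusive ``k_range`` via
    :func:`kmeans_cluster`; the chosen K is the interior candidate
    maximizing the discrete curvature ``SSE(K-1) - 2*SSE(K) + SSE(K+1)``
    (the point where the decrease "suddenly changes"). Returns the chosen K
    and the full SSE curve for inspection.
    """
    k_lo, k_hi = k_range
    ks = np.arange(k_lo, k_hi + 1)
    if len(ks) < 3:
        raise ValueError("elbow selection needs at least 3 candidate K values")
    if k_lo < 1 or k_hi > len(cloud):
        raise ValueError(f"k_range {k_range} outside [1, N={len(cloud)}]")
    sse = np.array([
        kmeans_cluster(cloud, int(k), seed=seed, n_restarts=n_restarts).sse
        for k in ks
    ])
    curvature = sse[:-2] - 2 * sse[1:-1] + sse[2:]
    chosen = int(ks[1:-1][np.argmax(curvature)])
    return chosen, sse


def extract_pig_cluster(
    cloud: PointCloud,
    seg: SegmentationResult,
    camera_axis: str = "z",
    camera_sign: int = 1,
) -> PointCloud:
    """Return the cluster nearest the overhead camera (the raised back).

    With a downward-looking camera the animal's back is the raised surface
    between floor and lens, so the pig is the cluster whose mean coordinate
    along ``camera_axis`` (times ``camera_sign``) is greatest. Ties are
    broken by larger point count. Colors are carried through.
    """
    if len(seg.labels) != len(cloud):
        raise ValueError(
            f"segmentation covers {len(seg.labels)} points, cloud has {len(cloud)}"
        )
    ax = _AXIS_INDEX[camera_axis]
    if camera_sign not in (1, -1):
        raise ValueError("camera_sign must be +1 or -1")
    coord = camera_sign * cloud.points[:, ax]
    elevations = np.array([coord[seg.labels == j].mean() for j in range(seg.K)])
    counts = np.bincount(seg.labels, minlength=seg.K)
    # lexicographic: max elevation, then max count
    order = np.lexsort((counts, elevations))
    pig = order[-1]
    return cloud.select(seg.labels == pig)
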