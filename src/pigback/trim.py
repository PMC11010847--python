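"""Head/tail removal by weighted local density.

The head and tail move during capture and reconstruct poorly, so they are
cut off before measuring the back. The procedure exploits a geometric fact
about down-looking captures: over the nearly flat top of the back, points
within a small horizontal block are tightly grouped, while over steep
structures — the flanks of the bulbous head and the tail root — a block's
points spread vertically. Blocks with large spread ("local density maxima"
in the weighted-density sense below) therefore outline the protrusions:

1. partition the cloud into a square horizontal grid of side 0.02 m;
2. score each block by the mean distance of its points to the block center,
   excluding the single farthest point (the weighted local density);
3. run DBSCAN (eps 0.5 m, min_samples 10) on the centers of high-density
   blocks to discard isolated noise blocks;
4. the clustered block centers with extreme projections onto the body axis
   are the head and tail endpoints;
5. remove all points within 0.4 m of either endpoint along the body axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .pc_io import PointCloud

__all__ = [
    "TrimParams",
    "Block",
    "BlockGrid",
    "TrimFailure",
    "TrimResult",
    "build_block_grid",
    "weighted_local_density",
    "dbscan",
    "locate_endpoints",
    "remove_head_tail",
    "principal_horizontal_axis",
]

logger = logging.getLogger(__name__)

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class TrimFailure(RuntimeError):
    """Signals that no usable density maxima were found; caller may skip trimming."""


@dataclass(frozen=True)
class TrimParams:
    """Parameters of the density-based trim.

    ``block_side``: horizontal grid cell side (m). ``dbscan_eps`` /
    ``dbscan_min_samples``: DBSCAN radius (m) and neighborhood size used to
    group high-density blocks. ``trim_extent``: length removed beyond each
    endpoint along the body axis (m). ``density_percentile``: blocks above
    this percentile of the density distribution count as density maxima.
    """

    block_side: float = 0.02
    dbscan_eps: float = 0.5
    dbscan_min_samples: int = 10
    trim_extent: float = 0.4
    density_percentile: float = 90.0

    def __post_init__(self):
        for name in ("block_side", "dbscan_eps", "trim_extent"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.dbscan_min_samples < 1:
            raise ValueError("dbscan_min_samples must be >= 1")
        if not 0 < self.density_percentile < 100:
            raise ValueError("density_percentile must lie in (0, 100)")


@dataclass
class Block:
    cell: tuple[int, int]
    indices: np.ndarray      # member point indices into the source cloud
    center: np.ndarray       # (3,) mean of member points
    density: float = 0.0


@dataclass
class BlockGrid:
    block_side: float
    blocks: list[Block] = field(default_factory=list)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.blocks])

    @property
    def densities(self) -> np.ndarray:
        return np.array([b.density for b in self.blocks])


def weighted_local_density(points: np.ndarray, center: np.ndarray) -> float:
    """Mean distance to the block center, excluding the farthest point.

    For n >= 2 member points with distances d_i to the center this is
    ``(sum(d_i) - max(d_i)) / (n - 1)``; blocks with a single point score 0.
    Discounting the farthest point robustifies the score against a stray
    outlier in the block.
    """
    n = len(points)
    if n <= 1:
        return 0.0
    d = np.linalg.norm(points - center, axis=1)
    return float((d.sum() - d.max()) / (n - 1))


def build_block_grid(
    cloud: PointCloud, block_side: float = 0.02, vertical_axis: str = "z"
) -> BlockGrid:
    """Partition the cloud by a square 2D grid over the horizontal plane.

    Each point belongs to exactly one block; the block center is the 3D mean
    of its members and its density the weighted local density score.
    """
    if len(cloud) == 0:
        raise ValueError("cannot build a block grid on an empty cloud")
    v = _AXIS_INDEX[vertical_axis]
    horiz = [a for a in range(3) if a != v]
    plane = cloud.points[:, horiz]
    origin = plane.min(axis=0)
    cells = np.floor((plane - origin) / block_side).astype(np.int64)
    uniq, inverse = np.unique(cells, axis=0, return_inverse=True)
    grid = BlockGrid(block_side=block_side)
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(len(uniq) + 1))
    for b in range(len(uniq)):
        idx = order[bounds[b]:bounds[b + 1]]
        pts = cloud.points[idx]
        center = pts.mean(axis=0)
        grid.blocks.append(Block(
            cell=tuple(uniq[b]),
            indices=idx,
            center=center,
            density=weighted_local_density(pts, center),
        ))
    return grid


def dbscan(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Density-based clustering by region query and expansion.

    Returns per-point labels; -1 marks noise. A point is a core point when
    its closed eps-ball contains at least ``min_samples`` points (itself
    included); clusters grow from core points through their neighborhoods.
    """
    n = len(points)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    tree = cKDTree(points)
    neighborhoods = tree.query_ball_point(points, eps)
    core = np.array([len(nb) >= min_samples for nb in neighborhoods])
    cluster = 0
    visited = np.zeros(n, dtype=bool)
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        # expand a new cluster from core point i
        stack = [i]
        visited[i] = True
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in neighborhoods[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                if not visited[k] and core[k]:
                    visited[k] = True
                    stack.append(k)
        cluster += 1
    return labels


def principal_horizontal_axis(
    points: np.ndarray, vertical_axis: str = "z"
) -> np.ndarray:
    """Unit body-length axis: largest-variance direction in the horizontal plane."""
    v = _AXIS_INDEX[vertical_axis]
    horiz = [a for a in range(3) if a != v]
    plane = points[:, horiz]
    cov = np.cov(plane.T)
    w, vecs = np.linalg.eigh(cov)
    u2 = vecs[:, np.argmax(w)]
    axis = np.zeros(3)
    axis[horiz] = u2
    # deterministic orientation: positive leading horizontal component
    if axis[horiz[0]] < 0 or (axis[horiz[0]] == 0 and axis[horiz[1]] < 0):
        axis = -axis
    return axis


def locate_endpoints(
    grid: BlockGrid, params: TrimParams, body_axis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Find the head and tail endpoints among density-maxima blocks.

    Blocks whose density exceeds the ``density_percentile`` of all block
    densities are clustered with DBSCAN; among non-noise blocks the centers
    with minimal and maximal projection onto ``body_axis`` are the
    endpoints. The endpoint whose neighborhood of density-maxima blocks is
    wider across the body axis is reported as the head (the head is the
    broader protrusion).

    Raises :class:`TrimFailure` when no or only one usable maxima block
    exists, or when DBSCAN marks everything as noise.
    """
    densities = grid.densities
    thresh = np.percentile(densities, params.density_percentile)
    cand = np.flatnonzero(densities > thresh)
    if len(cand) < 2:
        raise TrimFailure("fewer than 2 blocks above the density threshold")
    centers = grid.centers[cand]
    labels = dbscan(centers, params.dbscan_eps, params.dbscan_min_samples)
    keep = labels >= 0
    if not np.any(keep):
        raise TrimFailure("all high-density blocks classified as DBSCAN noise")
    centers = centers[keep]
    dens = densities[cand][keep]
    proj = centers @ body_axis
    lo, hi = np.argmin(proj), np.argmax(proj)
    if proj[hi] - proj[lo] <= 2 * params.trim_extent:
        # a single knot of maxima (or no real body span): trimming around
        # these endpoints would remove everything between them
        raise TrimFailure(
            "density maxima span is no longer than the two trim extents"
        )
    p_lo, p_hi = centers[lo], centers[hi]

    def _end_width(p):
        # cross-axis spread of maxima blocks near the endpoint: the head is
        # the broader protrusion, so its rim ring is wider across the axis
        near = np.abs(proj - p @ body_axis) <= 0.3
        if near.sum() < 2:
            return 0.0
        perp = centers[near] - np.outer(proj[near], body_axis)
        return float(np.ptp(perp, axis=0).max())

    if _end_width(p_lo) >= _end_width(p_hi):
        return p_lo, p_hi
    return p_hi, p_lo


@dataclass
class TrimResult:
    trimmed: PointCloud
    removed: PointCloud
    head_point: Optional[np.ndarray]
    tail_point: Optional[np.ndarray]
    applied: bool


def remove_head_tail(
    cloud: PointCloud,
    params: TrimParams = TrimParams(),
    vertical_axis: str = "z",
    trim_axis: Optional[str] = None,
) -> TrimResult:
    """Remove head and tail regions from the segmented pig cluster.

    The body axis defaults to the horizontal principal direction of the
    cloud; pass ``trim_axis`` ("x"/"y"/"z") to force a coordinate axis
    instead. Points whose axis projection lies within ``trim_extent`` of
    either endpoint's projection are moved to ``removed``; the rest form
    ``trimmed``. On trim failure the input is returned unchanged with an
    empty ``removed`` and a logged warning.
    """
    if len(cloud) == 0:
        raise ValueError("cannot trim an empty cloud")
    if trim_axis is None:
        axis = principal_horizontal_axis(cloud.points, vertical_axis)
    else:
        axis = np.zeros(3)
        axis[_AXIS_INDEX[trim_axis]] = 1.0
    grid = build_block_grid(cloud, params.block_side, vertical_axis)
    try:
        head, tail = locate_endpoints(grid, params, axis)
    except TrimFailure as exc:
        logger.warning("head/tail trim skipped: %s", exc)
        empty = PointCloud(np.empty((0, 3)),
                           np.empty((0, 3), dtype=np.int64) if cloud.has_colors else None,
                           source_id=cloud.source_id)
        return TrimResult(cloud, empty, None, None, applied=False)
    proj = cloud.points @ axis
    near_end = (
        (np.abs(proj - head @ axis) <= params.trim_extent)
        | (np.abs(proj - tail @ axis) <= params.trim_extent)
    )
    if near_end.all():
        logger.warning(
            "trim removed the entire cloud (body shorter than 2x trim_extent?)"
        )
    return TrimResult(
        trimmed=cloud.select(~near_end),
        removed=cloud.select(near_end),
        head_point=head,
        tail_point=tail,
        applied=True,
    )
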