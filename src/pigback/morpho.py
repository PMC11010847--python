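"""Pose correction and body-width extraction.

The trimmed back cloud is enclosed in a PCA oriented bounding box (OBB); if
the box's long axis deviates from the x direction in the horizontal plane
by more than a threshold (default 1 degree), the cloud is rotated about the
vertical axis to align it. The aligned back is then split into three equal
sections along x — shoulder, abdomen and hip regions — and each section's
width is the maximum transverse chord: within narrow x-bins, the spread
``y_max - y_min`` is computed and the section width is the largest bin
spread.

Also provides the error metrics used to score the pipeline: mean relative
error for widths, and MAE/MAPE/RMSE for weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pc_io import PointCloud

__all__ = [
    "OrientedBox",
    "BodyMeasurements",
    "DegenerateGeometryError",
    "MeasurementError",
    "fit_obb",
    "correct_pose",
    "measure_widths",
    "mean_relative_error",
    "regression_metrics",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class DegenerateGeometryError(ValueError):
    """Raised when a cloud is too degenerate for box fitting (collinear, N < 3)."""


class MeasurementError(ValueError):
    """Raised when a body section contains no points to measure."""


@dataclass
class OrientedBox:
    """A PCA-oriented bounding box.

    ``axes`` rows are orthonormal box axes ordered by non-increasing extent
    (row 0 = longest side); ``extents`` are full side lengths in meters;
    ``center`` is the box center.
    """

    center: np.ndarray
    axes: np.ndarray
    extents: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64)
        self.axes = np.asarray(self.axes, dtype=np.float64)
        self.extents = np.asarray(self.extents, dtype=np.float64)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("box axes must be orthonormal")
        if np.any(np.diff(self.extents) > 1e-12):
            raise ValueError("extents must be sorted non-increasing")

    def contains(self, points: np.ndarray, slack: float = 1e-6) -> np.ndarray:
        local = (points - self.center) @ self.axes.T
        return np.all(np.abs(local) <= self.extents / 2 + slack, axis=1)


@dataclass
class BodyMeasurements:
    """Shoulder/abdomen/hip widths (m) and the x-bounds of the three sections."""

    shoulder: float
    abdomen: float
    hip: float
    section_bounds: np.ndarray  # (4,) axis coordinates delimiting the sections

    def __post_init__(self):
        self.section_bounds = np.asarray(self.section_bounds, dtype=np.float64)
        if not (self.shoulder > 0 and self.abdomen > 0 and self.hip > 0):
            raise ValueError("all widths must be > 0")
        lengths = np.diff(self.section_bounds)
        if not np.allclose(lengths, lengths[0], atol=1e-9):
            raise ValueError("the three sections must have equal length")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.shoulder, self.abdomen, self.hip)


def fit_obb(cloud: PointCloud) -> OrientedBox:
    """Fit a covariance-eigenvector oriented bounding box.

    Axes are the principal directions of the point covariance; extents the
    projection ranges along them. Deterministic up to axis sign; signs are
    fixed so the long axis has a positive x component (falling back to y,
    then z when the leading components vanish) and the frame is
    right-handed.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise DegenerateGeometryError(f"OBB needs >= 3 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    w, vecs = np.linalg.eigh(cov)
    if w[1] <= max(w[2], 1.0) * 1e-12:
        raise DegenerateGeometryError("points are (nearly) collinear")
    axes = vecs.T[::-1]  # rows, descending eigenvalue
    proj = (pts - centroid) @ axes.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    extents = hi - lo
    order = np.argsort(-extents, kind="stable")
    axes, extents, lo, hi = axes[order], extents[order], lo[order], hi[order]

    def _orient(v):
        for c in v:
            if abs(c) > 1e-12:
                return v if c > 0 else -v
        return v

    a0 = _orient(axes[0])
    a1 = _orient(axes[1])
    a2 = np.cross(a0, a1)
    flipped = np.array([
        np.any(a0 != axes[0]), np.any(a1 != axes[1]),
        np.dot(a2, axes[2]) < 0,
    ])
    for i, f in enumerate(flipped):
        if f:
            lo[i], hi[i] = -hi[i], -lo[i]
    axes = np.vstack([a0, a1, a2])
    center = centroid + ((lo + hi) / 2) @ axes
    return OrientedBox(center=center, axes=axes, extents=extents)


def _horizontal_angle_deg(axis: np.ndarray, vertical: int) -> float:
    """Signed angle (deg) between an axis's horizontal projection and the
    first horizontal coordinate direction, wrapped to (-90, 90]."""
    horiz = [a for a in range(3) if a != vertical]
    u, v = axis[horiz[0]], axis[horiz[1]]
    ang = np.degrees(np.arctan2(v, u))
    if ang > 90:
        ang -= 180
    elif ang <= -90:
        ang += 180
    return float(ang)


def correct_pose(
    cloud: PointCloud,
    threshold_deg: float = 1.0,
    vertical_axis: str = "z",
) -> tuple[PointCloud, float]:
    """Null the horizontal tilt of the body's long axis.

    If the angle between the OBB long axis and the x direction (measured in
    the horizontal plane) exceeds ``threshold_deg``, the cloud is rotated
    about the vertical axis through its centroid to remove it; otherwise the
    cloud is returned unchanged. Returns ``(corrected, applied_deg)`` where
    ``applied_deg`` is the signed rotation actually applied (0 when within
    threshold). Pitch and roll are untouched.
    """
    box = fit_obb(cloud)
    v = _AXIS_INDEX[vertical_axis]
    ang = _horizontal_angle_deg(box.axes[0], v)
    if abs(ang) <= threshold_deg:
        return cloud, 0.0
    theta = -np.radians(ang)
    horiz = [a for a in range(3) if a != v]
    c, s = np.cos(theta), np.sin(theta)
    rot2 = np.array([[c, -s], [s, c]])
    centroid = cloud.points.mean(axis=0)
    pts = cloud.points - centroid
    pts[:, horiz] = pts[:, horiz] @ rot2.T
    pts += centroid
    return (
        PointCloud(pts, cloud.colors, source_id=cloud.source_id),
        float(np.degrees(theta)),
    )


def measure_widths(
    cloud: PointCloud,
    n_bins_per_section: int = 20,
    head_point: Optional[np.ndarray] = None,
) -> BodyMeasurements:
    """Extract shoulder/abdomen/hip widths from a pose-corrected cloud.

    The x-range is split into three equal sections; each section into
    ``n_bins_per_section`` x-bins; a bin's width is ``y_max - y_min`` over
    its points and a section's width the maximum over non-empty bins.
    Sections are mapped to anatomy by distance to ``head_point`` (nearest =
    shoulder, middle = abdomen, farthest = hip); without a head point the
    low-x section is taken as the shoulder.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise MeasurementError("too few points to measure")
    x = pts[:, 0]
    x_lo, x_hi = x.min(), x.max()
    bounds = np.linspace(x_lo, x_hi, 4)
    widths = []
    for s in range(3):
        lo, hi = bounds[s], bounds[s + 1]
        in_sec = (x >= lo) & (x <= hi) if s == 2 else (x >= lo) & (x < hi)
        if not np.any(in_sec):
            raise MeasurementError(f"section {s} ({lo:.3f}..{hi:.3f} m) is empty")
        edges = np.linspace(lo, hi, n_bins_per_section + 1)
        bins = np.clip(np.searchsorted(edges, x[in_sec], "right") - 1,
                       0, n_bins_per_section - 1)
        y = pts[in_sec, 1]
        best = 0.0
        for b in np.unique(bins):
            yy = y[bins == b]
            best = max(best, float(yy.max() - yy.min()))
        widths.append(best)
    if head_point is not None:
        mids = (bounds[:-1] + bounds[1:]) / 2
        order = np.argsort(np.abs(mids - head_point[0]))  # nearest first
    else:
        order = np.array([0, 1, 2])
    return BodyMeasurements(
        shoulder=widths[order[0]],
        abdomen=widths[order[1]],
        hip=widths[order[2]],
        section_bounds=bounds,
    )


def mean_relative_error(true_vals, est_vals) -> float:
    """100 * mean(|true - est| / |true|), the width-accuracy metric (%)."""
    t = np.asarray(true_vals, dtype=np.float64)
    e = np.asarray(est_vals, dtype=np.float64)
    if t.shape != e.shape or t.size < 1:
        raise ValueError("inputs must be equal-length, non-empty vectors")
    if np.any(t == 0):
        raise ZeroDivisionError("true values must be nonzero")
    return float(100.0 * np.mean(np.abs(t - e) / np.abs(t)))


def regression_metrics(true_w, pred_w) -> tuple[float, float, float]:
    """Weight-model metrics: (MAE kg, MAPE %, RMSE kg)."""
    t = np.asarray(true_w, dtype=np.float64)
    p = np.asarray(pred_w, dtype=np.float64)
    if t.shape != p.shape or t.size < 1:
        raise ValueError("true and predicted weights must have equal length >= 1")
    if np.any(t <= 0):
        raise ValueError("true weights must be positive")
    d = p - t
    mae = float(np.mean(np.abs(d)))
    mape = float(100.0 * np.mean(np.abs(d) / t))
    rmse = float(np.sqrt(np.mean(d ** 2)))
    return mae, mape, rmse
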