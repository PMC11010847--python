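"""End-to-end automation: configuration, staged pipeline and batch runs.

Wires the stages into the single automated flow a pen-gate installation
needs: filter -> segment -> trim -> pose-correct -> measure -> (optionally)
predict weight, with per-stage point counts and wall times collected into a
machine-readable report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import model as model_mod
from .morpho import correct_pose, measure_widths
from .pc_io import PointCloud, read_ply
from .preprocess import (
    VoxelFilterParams, voxel_downsample, kmeans_cluster,
    elbow_select_k, extract_pig_cluster,
)
from .trim import TrimParams, remove_head_tail

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "run_batch"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of the automated pipeline.

    ``k`` may be an integer (default 3, the overhead-station operating point)
    or ``"auto"`` (elbow selection over
    ``[k_min, k_max]``). ``model_path`` enables weight prediction;
    without it the pipeline is measurement-only.
    """

    edgelength: float = 0.03
    k: Union[int, str] = 3
    k_min: int = 1
    k_max: int = 8
    camera_axis: str = "z"
    camera_sign: int = 1
    block_side: float = 0.02
    dbscan_eps: float = 0.5
    dbscan_min_samples: int = 10
    trim_extent: float = 0.4
    density_percentile: float = 90.0
    bins: int = 20
    angle_threshold_deg: float = 1.0
    model_path: Optional[str] = None
    feature_mode: str = "xyz"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.k, str) and self.k != "auto":
            raise ValueError("k must be an integer or 'auto'")

    def trim_params(self) -> TrimParams:
        return TrimParams(
            block_side=self.block_side,
            dbscan_eps=self.dbscan_eps,
            dbscan_min_samples=self.dbscan_min_samples,
            trim_extent=self.trim_extent,
            density_percentile=self.density_percentile,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineReport:
    """Per-run record: stage point counts, widths, weight and timings."""

    source: str
    stage_counts: dict = field(default_factory=dict)      # stage -> n points
    chosen_k: Optional[int] = None
    shoulder: Optional[float] = None
    abdomen: Optional[float] = None
    hip: Optional[float] = None
    weight: Optional[float] = None
    applied_rotation_deg: Optional[float] = None
    stage_seconds: dict = field(default_factory=dict)
    total_seconds: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class _StageTimer:
    def __init__(self, report: PipelineReport):
        self.report = report

    def run(self, name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        dt = time.perf_counter() - t0
        self.report.stage_seconds[name] = dt
        logger.info("stage %-8s %.3f s", name, dt)
        return out


def _rotate_about_vertical(point, center, deg, vertical=2):
    horiz = [a for a in range(3) if a != vertical]
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    p = np.array(point, dtype=np.float64) - center
    u, v = p[horiz[0]], p[horiz[1]]
    p[horiz[0]] = c * u - s * v
    p[horiz[1]] = s * u + c * v
    return p + center


def run_pipeline(
    ply_path_or_cloud, config: PipelineConfig = PipelineConfig()
) -> PipelineReport:
    """Run the full measurement (and optional weight-prediction) pipeline.

    Accepts a PLY path or an in-memory :class:`PointCloud`. Raises the
    underlying stage error on failure; the CLI maps these to exit codes.
    """
    t_start = time.perf_counter()
    if isinstance(ply_path_or_cloud, PointCloud):
        cloud = ply_path_or_cloud
        source = cloud.source_id or "<memory>"
    else:
        cloud = read_ply(ply_path_or_cloud)
        source = str(ply_path_or_cloud)
    report = PipelineReport(source=source)
    timer = _StageTimer(report)
    report.stage_counts["input"] = len(cloud)

    filtered = timer.run(
        "filter", voxel_downsample, cloud, VoxelFilterParams(config.edgelength)
    )
    report.stage_counts["filter"] = len(filtered)

    def _segment():
        if config.k == "auto":
            k, _ = elbow_select_k(
                filtered, (config.k_min, config.k_max), seed=config.seed
            )
        else:
            k = int(config.k)
        seg = kmeans_cluster(filtered, k, seed=config.seed)
        return k, extract_pig_cluster(
            filtered, seg, config.camera_axis, config.camera_sign
        )

    report.chosen_k, pig = timer.run("segment", _segment)
    report.stage_counts["segment"] = len(pig)

    trim_res = timer.run(
        "trim", remove_head_tail, pig, config.trim_params(),
        vertical_axis=config.camera_axis,
    )
    report.stage_counts["trim"] = len(trim_res.trimmed)
    back = trim_res.trimmed if len(trim_res.trimmed) else pig

    def _measure():
        corrected, applied = correct_pose(
            back, config.angle_threshold_deg, vertical_axis=config.camera_axis
        )
        head = trim_res.head_point
        if head is not None and applied != 0.0:
            head = _rotate_about_vertical(
                head, back.points.mean(axis=0), applied,
                vertical={"x": 0, "y": 1, "z": 2}[config.camera_axis],
            )
        meas = measure_widths(corrected, config.bins, head_point=head)
        return corrected, applied, meas

    corrected, applied, meas = timer.run("measure", _measure)
    report.applied_rotation_deg = applied
    report.shoulder, report.abdomen, report.hip = meas.as_tuple()

    if config.model_path is not None:
        def _predict():
            m = model_mod.load_model(config.model_path)
            # the checkpoint dictates the feature mode: it must match the
            # network's input width
            feats = model_mod.assemble_features(
                corrected, m.config.feature_mode, m.config.n_points, config.seed
            )
            return model_mod.predict(m, feats)
        report.weight = timer.run("predict", _predict)

    report.total_seconds = time.perf_counter() - t_start
    return report


def run_batch(
    inputs: Sequence, config: PipelineConfig = PipelineConfig()
) -> list[PipelineReport]:
    """Independent per-file pipeline runs; failures are isolated per input.

    Raises ``RuntimeError`` only when every input fails.
    """
    if len(inputs) == 0:
        raise ValueError("batch needs at least one input")
    reports, failures = [], []
    for item in inputs:
        try:
            reports.append(run_pipeline(item, config))
        except Exception as exc:  # noqa: BLE001 - isolate per-file failures
            logger.error("pipeline failed on %s: %s", item, exc)
            failures.append((item, exc))
    if not reports:
        raise RuntimeError(
            f"all {len(failures)} inputs failed; first error: {failures[0][1]}"
        )
    return reports
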