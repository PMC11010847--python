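"""Synthetic back-view scene generator with ground truth.

Farm recordings of sows under an overhead depth camera are emulated by a
parametric construction in the camera frame (z is depth: the camera sits at
the origin looking toward negative z; the floor lies near z = -2.5 m and
the animal's back near z = -1.6 m, matching the magnitudes a ceiling-mounted
RealSense produces).

A pig is the upper surface of a tapered elliptical cylinder:

* the half-width profile is piecewise linear through shoulder/abdomen/hip
  control values at the three section midpoints, with each transition placed
  inside the wider section so that the maximum chord of every third of the
  body equals its control width exactly — this makes the section widths
  recoverable ground truth rather than an approximation;
* bulbous head and tail caps (plan-circular domes) protrude beyond the
  torso ends; the head is the larger, steeper dome. Their steep rims are the
  structures the density-based trimmer is designed to find;
* Gaussian coordinate noise emulates depth-sensor error; per-point RGB
  follows a configurable base color and along-body gradient.

A scene embeds the animal in the measurement station the way the camera
sees it: a circular field-of-view crop (a cone-FOV depth sensor gated to
the station yields a round footprint), the floor with the animal's
self-occlusion shadow removed (a nadir camera cannot see the floor within
~0.13 m of the silhouette), and one or two channel walls running parallel
to the body. These geometric facts matter: they are what makes the pig a
single compact structure relative to the background, i.e. what makes
coordinate K-means segmentation of overhead captures work at all.

Weights follow a generic allometric volume-proxy law so that shape
determines weight up to noise. Every point carries a ground-truth label
(pig/head/tail/floor/fence) and every sample a ground-truth (widths,
weight, yaw).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .pc_io import PointCloud

__all__ = [
    "PigSpec",
    "FenceSpec",
    "SceneTruth",
    "SceneSample",
    "make_pig",
    "make_scene",
    "make_blob_scene",
    "allometric_weight",
    "sample_spec",
    "make_cohort",
]

# geometry constants of the construction (meters)
_ARCH_DROP = 0.18       # vertical drop from back ridge to torso side edge
_CAP_SEMI_X = 0.22      # cap along-body semi-axis (head/neck, rump/tail length)
_CAP_OFFSET = 0.18      # cap center distance beyond the torso end
_HEAD_DROP = 0.13       # vertical drop across the head dome
_TAIL_DROP = 0.11       # vertical drop across the tail dome
_HEAD_TOP = -0.02       # head dome apex below the back ridge
_TAIL_TOP = -0.03
_END_TAPER = 0.75       # half-width fraction remaining at the torso ends
_OCCLUSION = 0.15       # floor invisible within this margin of the silhouette
_FOV_MARGIN = 0.0      # circular crop radius beyond the nose tip
_PLATFORM = 0.12       # weighbridge platform height; the animal stands on it


@dataclass(frozen=True)
class PigSpec:
    """Parameters of one synthetic animal (meters, degrees, RGB in 0-255)."""

    body_length: float = 1.60
    shoulder_width: float = 0.40
    abdomen_width: float = 0.42
    hip_width: float = 0.38
    back_height: float = 0.85        # back ridge height above the floor
    head_bulge: float = 0.15         # head cap plan radius
    tail_bulge: float = 0.09         # tail cap plan radius
    noise_sigma: float = 0.005      # coordinate noise, m
    points_per_m2: float = 24000.0  # sampling density over the plan footprint
    yaw_deg: float = 0.0
    base_color: tuple = (150, 120, 110)
    color_gradient: tuple = (20.0, 10.0, 5.0)   # RGB change per meter along body
    seed: int = 0

    def __post_init__(self):
        if not 1.0 < self.body_length < 2.2:
            raise ValueError("body_length must lie in (1.0, 2.2) m")
        for name in ("shoulder_width", "abdomen_width", "hip_width"):
            if not 0.2 < getattr(self, name) < 0.7:
                raise ValueError(f"{name} must lie in (0.2, 0.7) m")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.points_per_m2 <= 0 or self.back_height <= 0:
            raise ValueError("points_per_m2 and back_height must be > 0")
        if self.head_bulge <= 0 or self.tail_bulge <= 0:
            raise ValueError("bulge radii must be > 0")

    @property
    def widths(self) -> tuple[float, float, float]:
        return (self.shoulder_width, self.abdomen_width, self.hip_width)

    @property
    def nose_tip(self) -> float:
        """Distance from body center to the head cap's far edge."""
        return self.body_length / 2 + _CAP_OFFSET + _CAP_SEMI_X


@dataclass(frozen=True)
class FenceSpec:
    """A channel wall: a vertical slab parallel to the body axis."""

    side: int = 1                    # +1: positive-y wall, -1: negative-y wall
    height: float = 0.5              # m above the floor
    color: tuple = (140, 140, 60)


@dataclass
class SceneTruth:
    widths: tuple[float, float, float]
    weight: float
    yaw_deg: float
    head_apex: Optional[np.ndarray] = None   # outermost head-cap base point
    tail_apex: Optional[np.ndarray] = None


@dataclass
class SceneSample:
    cloud: PointCloud
    labels: np.ndarray               # per-point {pig, head, tail, floor, fence}
    truth: SceneTruth
    spec: PigSpec


def _half_width_profile(spec: PigSpec, x: np.ndarray) -> np.ndarray:
    """Half-width at body coordinate x (x=0 at body center).

    Piecewise linear through the control half-widths at the three section
    midpoints; each shoulder<->abdomen / abdomen<->hip transition occupies
    the quarter-section adjacent to the boundary *inside the wider section*,
    so the maximum width over each third equals its control value. Beyond
    the outer midpoints the body tapers linearly to ``_END_TAPER`` of the
    end width.
    """
    L = spec.body_length
    s = L / 3
    mids = [-s, 0.0, s]
    # the head cap sits at +x, so anatomy runs hip -> abdomen -> shoulder
    # along increasing x (the shoulder section is adjacent to the head)
    widths = [spec.hip_width / 2, spec.abdomen_width / 2, spec.shoulder_width / 2]
    knots_x = [-L / 2, mids[0]]
    knots_w = [widths[0] * _END_TAPER, widths[0]]
    for j in (0, 1):
        b = (mids[j] + mids[j + 1]) / 2  # section boundary
        if widths[j] <= widths[j + 1]:
            knots_x += [b, b + s / 4]    # transition in the wider right section
        else:
            knots_x += [b - s / 4, b]
        knots_w += [widths[j], widths[j + 1]]
        knots_x.append(mids[j + 1])
        knots_w.append(widths[j + 1])
    knots_x.append(L / 2)
    knots_w.append(widths[2] * _END_TAPER)
    return np.interp(x, knots_x, knots_w)


def _sample_body(spec: PigSpec, rng) -> tuple[np.ndarray, np.ndarray, dict]:
    """Noise-free animal surface in the body frame (ridge at z=0).

    Returns (xyz, labels, apices); apices maps head/tail to the outermost
    cap base point along the body axis.
    """
    L = spec.body_length
    xs = np.linspace(-L / 2, L / 2, 200)
    area = 2 * np.trapezoid(_half_width_profile(spec, xs), xs)
    n_t = max(10, int(round(spec.points_per_m2 * area)))
    xt = rng.uniform(-L / 2, L / 2, n_t)
    hw = _half_width_profile(spec, xt)
    yt = rng.uniform(-1, 1, n_t) * hw
    frac = np.clip(np.abs(yt) / hw, 0, 1)
    zt = -_ARCH_DROP * (1 - np.sqrt(1 - frac ** 2))
    parts = [np.column_stack([xt, yt, zt])]
    labels = [np.full(n_t, "pig")]
    apices = {}
    # head and tail: elliptical domes running from the torso end outward;
    # the apex (density-trim target) sits ~0.4 m beyond the torso end so a
    # 0.4 m trim from it removes the cap and spares the torso
    for name, semi_y, drop, top, sign in (
        ("head", spec.head_bulge, _HEAD_DROP, _HEAD_TOP, 1),
        ("tail", spec.tail_bulge, _TAIL_DROP, _TAIL_TOP, -1),
    ):
        cx = sign * (L / 2 + _CAP_OFFSET)
        n_c = max(5, int(round(spec.points_per_m2 * np.pi * _CAP_SEMI_X * semi_y)))
        rho = np.sqrt(rng.uniform(size=n_c))
        th = rng.uniform(0, 2 * np.pi, n_c)
        ex, ey = rho * np.cos(th), rho * np.sin(th)   # unit-disc coordinates
        z = top - drop * (1 - np.sqrt(1 - rho ** 2))
        parts.append(np.column_stack(
            [cx + _CAP_SEMI_X * ex, semi_y * ey, z]
        ))
        labels.append(np.full(n_c, name))
        apices[name] = np.array(
            [cx + sign * _CAP_SEMI_X, 0.0, top - drop]
        )
    return np.vstack(parts), np.concatenate(labels), apices


def _pig_colors(spec: PigSpec, body_x: np.ndarray, rng) -> np.ndarray:
    col = (
        np.asarray(spec.base_color, dtype=np.float64)[None, :]
        + np.asarray(spec.color_gradient)[None, :] * body_x[:, None]
        + rng.normal(0, 4.0, size=(len(body_x), 3))
    )
    return np.clip(np.rint(col), 0, 255).astype(np.int64)


def _finish(spec: PigSpec, xyz, labels, colors, apices, floor_depth=2.5):
    """Apply sensor noise, yaw and camera-frame placement; build the sample."""
    rng = np.random.default_rng(spec.seed + 2)
    xyz = xyz + rng.normal(0, spec.noise_sigma, size=xyz.shape)
    th = np.radians(spec.yaw_deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    xyz = xyz @ R.T
    z_ridge = -(floor_depth - spec.back_height)
    xyz[:, 2] += z_ridge
    shifted = {}
    for k, v in apices.items():
        shifted[k] = R @ v + np.array([0, 0, z_ridge])
    truth = SceneTruth(
        widths=spec.widths,
        weight=allometric_weight(spec),
        yaw_deg=spec.yaw_deg,
        head_apex=shifted.get("head"),
        tail_apex=shifted.get("tail"),
    )
    cloud = PointCloud(xyz, colors, source_id=f"synthetic-{spec.seed}")
    return SceneSample(cloud=cloud, labels=labels, truth=truth, spec=spec)


def make_pig(spec: PigSpec) -> SceneSample:
    """Generate the animal-only cloud (back shell + head/tail caps)."""
    rng = np.random.default_rng(spec.seed)
    xyz, labels, apices = _sample_body(spec, rng)
    colors = _pig_colors(spec, xyz[:, 0], rng)
    return _finish(spec, xyz, labels, colors, apices)


def make_scene(
    spec: PigSpec,
    floor_depth: float = 2.5,
    fence_specs: Sequence[FenceSpec] = (FenceSpec(side=1), FenceSpec(side=-1)),
) -> SceneSample:
    """Animal + floor + channel walls inside a circular camera footprint.

    The floor is the plane ``z = -floor_depth`` clipped to the circular
    field of view (radius = nose tip + a small margin) with the animal's
    occlusion shadow removed. Walls are vertical slabs parallel to the body
    at 78% of the crop radius, spanning the central half of the footprint.
    The whole station yaws together with the animal (the body walks along
    the channel; the camera mount sets the residual angle).
    """
    if floor_depth <= spec.back_height:
        raise ValueError("floor must lie below the pig's back along the camera axis")
    rng = np.random.default_rng(spec.seed)
    body_xyz, body_lab, apices = _sample_body(spec, rng)
    colors = [_pig_colors(spec, body_xyz[:, 0], rng)]
    parts = [body_xyz]
    labs = [body_lab]
    L = spec.body_length
    R = spec.nose_tip + _FOV_MARGIN
    wall_y = 0.78 * R
    if max(spec.widths) / 2 + _OCCLUSION >= wall_y:
        raise ValueError("animal silhouette overlaps the channel walls")
    # the animal stands on the weighbridge platform: its feet (and back)
    # are a platform height above the channel floor; the platform itself
    # lies inside the occlusion shadow and is never visible
    z_floor = -(spec.back_height + _PLATFORM)  # body frame: ridge at 0
    # projective sampling: a depth camera spreads a fixed pixel budget over
    # solid angle, so per-area point density falls as 1/depth^2; the floor
    # and walls are farther from the lens than the back ridge
    ridge_depth = floor_depth - spec.back_height - _PLATFORM
    floor_scale = (ridge_depth / floor_depth) ** 2
    n_f = int(round(spec.points_per_m2 * floor_scale * np.pi * R ** 2))
    rho = R * np.sqrt(rng.uniform(size=n_f))
    th = rng.uniform(0, 2 * np.pi, n_f)
    fx, fy = rho * np.cos(th), rho * np.sin(th)
    hw = _half_width_profile(spec, np.clip(fx, -L / 2, L / 2))

    def _cap_shadow(sign, semi_y):
        cx = sign * (L / 2 + _CAP_OFFSET)
        return (
            ((fx - cx) / (_CAP_SEMI_X + _OCCLUSION)) ** 2
            + (fy / (semi_y + _OCCLUSION)) ** 2
        ) <= 1.0

    shadow = (
        ((np.abs(fx) <= L / 2 + _OCCLUSION) & (np.abs(fy) <= hw + _OCCLUSION))
        | _cap_shadow(1, spec.head_bulge)
        | _cap_shadow(-1, spec.tail_bulge)
    )
    vis = ~shadow
    n_vis = int(vis.sum())
    parts.append(np.column_stack([fx[vis], fy[vis], np.full(n_vis, z_floor)]))
    labs.append(np.full(n_vis, "floor"))
    colors.append(np.clip(np.rint(
        np.array([90.0, 90.0, 95.0]) + rng.normal(0, 5, size=(n_vis, 3))
    ), 0, 255).astype(np.int64))
    for f in fence_specs:
        half_len = 0.5 * R
        wall_depth = floor_depth - f.height / 2
        wall_scale = (ridge_depth / wall_depth) ** 2
        n_w = int(round(spec.points_per_m2 * wall_scale * 2 * half_len * f.height))
        wx = rng.uniform(-half_len, half_len, n_w)
        wz = z_floor + rng.uniform(0, f.height, n_w)
        parts.append(np.column_stack([wx, np.full(n_w, f.side * wall_y), wz]))
        labs.append(np.full(n_w, "fence"))
        colors.append(np.clip(np.rint(
            np.asarray(f.color, dtype=np.float64) + rng.normal(0, 5, size=(n_w, 3))
        ), 0, 255).astype(np.int64))
    sample = _finish(
        spec, np.vstack(parts), np.concatenate(labs), np.vstack(colors),
        apices, floor_depth,
    )
    sample.cloud.source_id = f"synthetic-scene-{spec.seed}"
    return sample


def make_blob_scene(
    n_blobs: int = 4,
    seed: int = 0,
    points_per_blob: int = 400,
    blob_sigma: float = 0.05,
    min_separation: float = 0.8,
) -> tuple[PointCloud, np.ndarray]:
    """Well-separated compact Gaussian blobs with known component count.

    The construction used to exercise cluster-count selection: isotropic
    blobs whose separation dwarfs their internal spread. Up to 4 blobs are
    placed on a regular simplex (all pairwise distances equal), which makes
    the SSE-vs-K curve exactly linear before the true component count and
    flat after it — the sharpest possible elbow at K = n_blobs. Beyond 4
    blobs (where equidistance is impossible in 3D) centers are drawn by
    rejection with a minimum separation. Returns the cloud and per-point
    blob indices.
    """
    rng = np.random.default_rng(seed)
    if n_blobs <= 4:
        simplex = np.array([
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ])[:n_blobs]
        # scale so every pairwise distance equals 1.5 * min_separation
        simplex = simplex / np.sqrt(8.0) * (1.5 * min_separation)
        centers = list(simplex + rng.normal(0, 0.01, size=simplex.shape))
    else:
        centers = []
        while len(centers) < n_blobs:
            cand = rng.uniform(-1.5, 1.5, size=3)
            if all(np.linalg.norm(cand - c) >= min_separation for c in centers):
                centers.append(cand)
    pts, lab = [], []
    for i, c in enumerate(centers):
        pts.append(c + rng.normal(0, blob_sigma, size=(points_per_blob, 3)))
        lab.append(np.full(points_per_blob, i))
    return PointCloud(np.vstack(pts)), np.concatenate(lab)


def allometric_weight(
    spec: PigSpec,
    a: float = 430.0,
    b: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> float:
    """Body weight (kg) from a volume-proxy power law.

    ``weight = a * (body_length * mean_width * back_height)**b + noise``.
    The defaults place specs sampled over the adult-sow width range in
    roughly 150-350 kg. This is a generic allometric stand-in that makes
    weight a recoverable function of shape, not a fitted sow growth model.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be > 0")
    volume = spec.body_length * float(np.mean(spec.widths)) * spec.back_height
    w = a * volume ** b
    if noise_sd > 0:
        w += float(np.random.default_rng(seed).normal(0, noise_sd))
    return float(w)


def sample_spec(
    rng: np.random.Generator,
    color_informative: bool = True,
    max_yaw_deg: float = 30.0,
    noise_sigma: float = 0.005,
    points_per_m2: float = 24000.0,
) -> PigSpec:
    """Draw one random sow spec from the cohort distributions.

    A common size scalar drives length, widths and height (so the cohort
    spans the adult-sow weight range coherently); when
    ``color_informative`` is set the base color brightness also tracks the
    size scalar, giving RGB features genuine information about weight; the
    negative-control preset draws brightness independently.
    """
    s = rng.uniform(0.85, 1.15)
    jitter = lambda lo, hi: rng.uniform(lo, hi)
    brightness = (
        90 + 140 * (s - 0.85) / 0.30 if color_informative
        else rng.uniform(90, 230)
    )
    return PigSpec(
        body_length=1.60 * s * jitter(0.96, 1.04),
        shoulder_width=0.40 * s * jitter(0.94, 1.06),
        abdomen_width=0.42 * s * jitter(0.95, 1.05),
        hip_width=0.38 * s * jitter(0.94, 1.06),
        back_height=0.85 * s * jitter(0.97, 1.03),
        head_bulge=0.15 * min(max(s, 0.9), 1.1),
        tail_bulge=0.09 * min(max(s, 0.9), 1.1),
        noise_sigma=noise_sigma,
        points_per_m2=points_per_m2,
        yaw_deg=rng.uniform(-max_yaw_deg, max_yaw_deg),
        base_color=(brightness, 0.85 * brightness, 0.80 * brightness),
        color_gradient=(20.0, 10.0, 5.0),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def make_cohort(
    n: int,
    seed: int = 0,
    frames_per_animal: int = 1,
    color_informative: bool = True,
    weight_noise_sd: float = 5.0,
    scenes: bool = False,
    **spec_kwargs,
) -> list[SceneSample]:
    """Generate ``n`` animals (optionally several noise-refreshed frames each).

    Weights get independent Gaussian scale noise of ``weight_noise_sd`` kg on
    top of the allometric law; frames of the same animal share spec and
    weight but have fresh sensor sampling.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = sample_spec(rng, color_informative=color_informative, **spec_kwargs)
        weight = allometric_weight(
            spec, noise_sd=weight_noise_sd, seed=int(rng.integers(0, 2 ** 31 - 1))
        )
        for f in range(frames_per_animal):
            fspec = spec if f == 0 else replace(
                spec, seed=int(rng.integers(0, 2 ** 31 - 1))
            )
            sample = make_scene(fspec) if scenes else make_pig(fspec)
            sample.truth.weight = weight
            out.append(sample)
    return out
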