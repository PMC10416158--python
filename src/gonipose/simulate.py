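"""Synthetic skeleton + camera simulator.

Emulates the acquisition geometry of a standing-subject shoulder-abduction
recording: a cohort of adult subjects (height ~ N(166.3, 8.1) cm) performs
right-shoulder abduction over a 10-160 degree grid in the coronal plane while
a camera films from a 3 m circle at 1.5 m height, at yaw angles between -30
and +45 degrees (positive = camera to the subject's right).  Frames are
rendered by pinhole perspective projection into normalized image coordinates,
re-centered on the mid-hip point, with a depth channel normalized by trunk
length so all three coordinates are scale-free.

The landmark noise model is additive Gaussian jitter plus a systematic
displacement of the right shoulder and elbow that grows linearly with
abduction angle and camera obliquity, mimicking how pose-network error
increases for raised arms and oblique views.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import ProjectionError, ValidationError
from .landmarks import Landmark, LandmarkFrame

__all__ = [
    "SubjectSpec",
    "CameraSpec",
    "NoiseSpec",
    "DatasetConfig",
    "sample_subject",
    "skeleton_3d",
    "project_frame",
    "generate_dataset",
]

# Namespaces keeping subject-anthropometry and frame-noise streams independent.
_SUBJECT_NS = 101
_FRAME_NS = 202

# Cohort anthropometry (fractions of standing height).
MEAN_HEIGHT_CM = 166.3
SD_HEIGHT_CM = 8.1
HEIGHT_RANGE_CM = (145.0, 195.0)
_HIP_HEIGHT_FRAC = 0.53  # greater trochanter height

# Monocular depth estimates flatten the scene; the emitted z channel carries
# this fraction of the true (angular-unit) depth offset.
_DEPTH_GAIN = 0.5


@dataclass(frozen=True)
class SubjectSpec:
    """Anthropometry of one synthetic subject.

    Segment lengths are fractions of standing height; defaults are standard
    adult body-segment proportions, individually jittered by ``sample_subject``.
    """

    height_cm: float = MEAN_HEIGHT_CM
    shoulder_width_frac: float = 0.230
    hip_width_frac: float = 0.180
    upper_arm_frac: float = 0.186
    trunk_frac: float = 0.288
    head_offset_frac: float = 0.130
    seed: int = 0

    def __post_init__(self):
        if not (100.0 <= self.height_cm <= 250.0):
            raise ValidationError(f"implausible height_cm {self.height_cm}")
        for name in (
            "shoulder_width_frac",
            "hip_width_frac",
            "upper_arm_frac",
            "trunk_frac",
            "head_offset_frac",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class CameraSpec:
    """Camera placement on a horizontal circle around the subject."""

    yaw_deg: float = 0.0
    distance_m: float = 3.0
    height_m: float = 1.5
    vertical_fov_deg: float = 65.0
    portrait: bool = True

    def __post_init__(self):
        if self.distance_m <= 0:
            raise ValidationError("distance_m must be positive")
        if not -90.0 <= self.yaw_deg <= 90.0:
            raise ValidationError("yaw_deg must lie in [-90, 90]")


@dataclass(frozen=True)
class NoiseSpec:
    """Landmark perturbation model (all magnitudes in normalized image units)."""

    sigma_xy: float = 0.003
    sigma_z_factor: float = 3.0
    bias_abduction_coef: float = 0.004
    bias_yaw_coef: float = 0.003
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_xy", "sigma_z_factor", "bias_abduction_coef", "bias_yaw_coef"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(sigma_xy=0.0, sigma_z_factor=0.0, bias_abduction_coef=0.0, bias_yaw_coef=0.0)


@dataclass(frozen=True)
class DatasetConfig:
    """Full generative description of a synthetic recording campaign."""

    n_subjects: int = 10
    camera_yaws_deg: tuple[float, ...] = (-30.0, -15.0, 0.0, 15.0, 30.0, 45.0)
    abduction_grid_deg: tuple[float, ...] = tuple(float(a) for a in range(10, 161, 10))
    frames_per_condition: int = 20
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    camera: CameraSpec = field(default_factory=CameraSpec)
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.frames_per_condition < 1:
            raise ValidationError("counts must be positive")
        if not self.camera_yaws_deg or not self.abduction_grid_deg:
            raise ValidationError("camera yaw and abduction grids must be non-empty")

    @property
    def n_frames(self) -> int:
        return (
            self.n_subjects
            * len(self.camera_yaws_deg)
            * len(self.abduction_grid_deg)
            * self.frames_per_condition
        )


def sample_subject(master_seed: int, index: int) -> SubjectSpec:
    """Draw one subject's anthropometry, deterministic in (master_seed, index).

    Height is Gaussian around the cohort mean, truncated by resampling;
    segment fractions get independent ~4% log-normal jitter so subjects have
    genuinely distinct proportions.
    """
    if index < 0:
        raise ValidationError("subject index must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, _SUBJECT_NS, index]))
    height = float(rng.normal(MEAN_HEIGHT_CM, SD_HEIGHT_CM))
    while not (HEIGHT_RANGE_CM[0] <= height <= HEIGHT_RANGE_CM[1]):
        height = float(rng.normal(MEAN_HEIGHT_CM, SD_HEIGHT_CM))
    base = SubjectSpec()
    jitter = lambda v: float(v * math.exp(rng.normal(0.0, 0.04)))  # noqa: E731
    return SubjectSpec(
        height_cm=height,
        shoulder_width_frac=jitter(base.shoulder_width_frac),
        hip_width_frac=jitter(base.hip_width_frac),
        upper_arm_frac=jitter(base.upper_arm_frac),
        trunk_frac=jitter(base.trunk_frac),
        head_offset_frac=jitter(base.head_offset_frac),
        seed=index,
    )


def skeleton_3d(subject: SubjectSpec, abduction_deg: float) -> dict[str, np.ndarray]:
    """3D keypoint positions in meters, floor origin, subject facing +x.

    World axes: x toward the yaw-0 camera, y to the subject's left, z up.
    The right upper arm is rotated ``abduction_deg`` away from the downward
    trunk axis within the coronal (y-z) plane; the left arm hangs at 0; the
    elbow stays straight.
    """
    if not 0.0 <= abduction_deg <= 180.0:
        raise ValidationError(f"abduction_deg {abduction_deg} outside [0, 180]")
    h = subject.height_cm / 100.0
    hip_z = _HIP_HEIGHT_FRAC * h
    shoulder_z = hip_z + subject.trunk_frac * h
    half_sw = subject.shoulder_width_frac * h / 2.0
    half_hw = subject.hip_width_frac * h / 2.0
    ua = subject.upper_arm_frac * h
    theta = math.radians(abduction_deg)

    # Subject's right is -y when facing +x with z up.
    pts = {
        "right_hip": np.array([0.0, -half_hw, hip_z]),
        "left_hip": np.array([0.0, +half_hw, hip_z]),
        "right_shoulder": np.array([0.0, -half_sw, shoulder_z]),
        "left_shoulder": np.array([0.0, +half_sw, shoulder_z]),
    }
    arm_dir = np.array([0.0, -math.sin(theta), -math.cos(theta)])
    pts["right_elbow"] = pts["right_shoulder"] + ua * arm_dir
    pts["left_elbow"] = pts["left_shoulder"] + np.array([0.0, 0.0, -ua])

    # Stylized head: nose well forward of the ear axis and ears slightly above
    # nose level.  These offsets are chosen so the projected face angles vary
    # strictly monotonically with camera yaw over the whole [-30, 45] degree
    # installation range (a forward nose makes the nose-to-shoulder ray swing
    # dominate; raised ears keep the nose-to-ear ray away from degenerate
    # alignment with it).
    d = subject.head_offset_frac * h
    head_center = np.array([0.0, 0.0, shoulder_z + d])
    pts["nose"] = head_center + np.array([0.60 * d, 0.0, 0.0])
    pts["right_ear"] = head_center + np.array([0.0, -0.80 * d, 0.20 * d])
    pts["left_ear"] = head_center + np.array([0.0, +0.80 * d, 0.20 * d])
    return pts


def _camera_basis(camera: CameraSpec, target: np.ndarray):
    """Camera position and (forward, right, down) orthonormal basis.

    The camera sits on its yaw circle and aims horizontally at the target's
    ground position (optical axis parallel to the floor).
    """
    phi = math.radians(camera.yaw_deg)
    pos = np.array(
        [
            camera.distance_m * math.cos(phi),
            -camera.distance_m * math.sin(phi),
            camera.height_m,
        ]
    )
    fwd = np.array([target[0] - pos[0], target[1] - pos[1], 0.0])
    n = np.linalg.norm(fwd)
    if n == 0:
        raise ProjectionError("camera is directly above the target")
    fwd /= n
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(fwd, up)
    right /= np.linalg.norm(right)
    down = np.cross(fwd, right)
    return pos, fwd, right, down


def project_frame(
    skeleton: dict[str, np.ndarray],
    camera: CameraSpec,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    *,
    abduction_deg: float | None = None,
    subject_id: str = "synthetic",
    frame_index: int = 0,
) -> LandmarkFrame:
    """Render one skeleton through the camera into a landmark frame.

    Coordinates are normalized image units re-centered on the mid-hip point
    (x right, y down); z is camera depth relative to the mid-hip, divided by
    the 3D right-trunk length so it shares the scale-free property of x, y.
    """
    if noise is None:
        noise = NoiseSpec.zero()
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    trunk_center = 0.25 * (
        skeleton["right_shoulder"]
        + skeleton["left_shoulder"]
        + skeleton["right_hip"]
        + skeleton["left_hip"]
    )
    pos, fwd, right, down = _camera_basis(camera, trunk_center)

    # Isotropic normalized units: both axes share the image-height scale, so
    # planar angles are not distorted by the sensor aspect ratio.  The
    # ``portrait`` flag is device-orientation metadata (it sets the horizontal
    # field extent, which the default 3 m geometry never approaches).
    f = 0.5 / math.tan(math.radians(camera.vertical_fov_deg) / 2.0)

    def proj(p: np.ndarray) -> tuple[float, float, float]:
        rel = p - pos
        depth = float(rel @ fwd)
        if depth <= 0:
            raise ProjectionError("landmark at or behind the camera plane")
        return f * float(rel @ right) / depth, f * float(rel @ down) / depth, depth

    raw = {name: proj(p) for name, p in skeleton.items()}
    mid_hip = tuple(
        (a + b) / 2.0 for a, b in zip(raw["right_hip"], raw["left_hip"])
    )

    theta = 0.0 if abduction_deg is None else abduction_deg
    bias = noise.bias_abduction_coef * (theta / 160.0) + noise.bias_yaw_coef * (
        abs(camera.yaw_deg) / 45.0
    )

    # Depth is expressed in the same angular image units as x and y
    # (f * depth-offset / hip depth), then compressed by _DEPTH_GAIN: monocular
    # depth estimates systematically flatten the scene, so 3D segment lengths
    # shrink under foreshortening instead of being rotation-invariant.
    lms: dict[str, Landmark] = {}
    for name, (u, v, depth) in raw.items():
        x = u - mid_hip[0] + float(rng.normal(0.0, noise.sigma_xy))
        y = v - mid_hip[1] + float(rng.normal(0.0, noise.sigma_xy))
        z = _DEPTH_GAIN * f * (depth - mid_hip[2]) / mid_hip[2] + float(
            rng.normal(0.0, noise.sigma_xy * noise.sigma_z_factor)
        )
        lms[name] = Landmark(name, x, y, z)

    if bias > 0.0:
        # Systematic pose-network drift for the raised right arm, the way
        # detection smears when the arm occludes the shoulder region: the
        # shoulder landmark drifts toward the trunk (medially and downward),
        # the elbow follows that drift rigidly and is additionally pulled
        # toward the shoulder (apparent arm shortening).
        sh, el = lms["right_shoulder"], lms["right_elbow"]
        mx, my = lms["left_shoulder"].x - sh.x, lms["left_shoulder"].y - sh.y
        mnorm = math.hypot(mx, my)
        med = (mx / mnorm, my / mnorm) if mnorm > 0 else (0.0, 0.0)
        drift = (0.75 * bias * med[0], 0.75 * bias * med[1] + 0.5 * bias)
        sh = Landmark("right_shoulder", sh.x + drift[0], sh.y + drift[1], sh.z)
        el = Landmark("right_elbow", el.x + drift[0], el.y + drift[1], el.z)
        dx, dy = sh.x - el.x, sh.y - el.y
        norm = math.hypot(dx, dy)
        if norm > 0:
            el = Landmark("right_elbow", el.x + bias * dx / norm, el.y + bias * dy / norm, el.z)
        lms["right_shoulder"] = sh
        lms["right_elbow"] = el

    return LandmarkFrame(
        landmarks=lms,
        subject_id=subject_id,
        frame_index=frame_index,
        true_abduction_deg=abduction_deg,
        camera_yaw_deg=camera.yaw_deg,
    )


def generate_dataset(config: DatasetConfig) -> list[LandmarkFrame]:
    """Generate the full labeled frame collection for a config.

    Frames are emitted subject-major, then camera yaw, then abduction angle,
    then repeat index; ``frame_index`` is a running counter per subject.  The
    result is fully deterministic given ``config.master_seed``.
    """
    return list(iter_dataset(config))


def iter_dataset(config: DatasetConfig) -> Iterator[LandmarkFrame]:
    for si in range(config.n_subjects):
        subject = sample_subject(config.master_seed, si)
        subject_id = f"S{si:02d}"
        frame_counter = 0
        for yi, yaw in enumerate(config.camera_yaws_deg):
            camera = replace(config.camera, yaw_deg=float(yaw))
            for ai, theta in enumerate(config.abduction_grid_deg):
                skeleton = skeleton_3d(subject, float(theta))
                for fi in range(config.frames_per_condition):
                    rng = np.random.default_rng(
                        np.random.SeedSequence(
                            [config.master_seed, _FRAME_NS, config.noise.seed, si, yi, ai, fi]
                        )
                    )
                    yield project_frame(
                        skeleton,
                        camera,
                        config.noise,
                        rng,
                        abduction_deg=float(theta),
                        subject_id=subject_id,
                        frame_index=frame_counter,
                    )
                    frame_counter += 1
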