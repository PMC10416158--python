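"""Geometric feature extraction from landmark frames.

Each frame yields one row of named, scale- and translation-invariant scalars:
length ratios between body segments, 2D and 3D joint angles, and the
cross-product trunk-size parameters.  Feature names follow the goniometry
literature's ``rt``/``lt`` (right/left) prefix convention.

Definitions (right side; left mirrors with sides swapped):

- ``rtarm_distratio``      |shoulderR->elbowR| / |shoulderR->hipR|
- ``rtelbowhip_distratio`` |elbowR->hipR|      / |shoulderR->hipR|
- ``rthip_distratio``      |shoulderR->hipR|   / |hipR->hipL|
- ``rtshoulder_distratio`` |shoulderR->shoulderL| / |shoulderR->hipR|
- ``rtshoulderAbduction``  planar angle between shoulderR->elbowR and the
  downward trunk midline (mid-shoulder -> mid-hip direction); the 3D variant
  ``rtshoulder_3Dabduction`` uses depth as well.  The trunk midline (rather
  than the per-side shoulder->hip ray) is the reference so the parameter reads
  as an anatomical abduction angle; under oblique projection the two
  references shear apart, which is exactly why both families are kept.
- ``rtshoulderAngle``      planar angle at the right shoulder between rays to
  the right elbow and right hip; ``rtshoulder_3Dangle`` is its 3D variant.
- ``rt_uppertrunkAngle`` / ``rt_lowertrunkAngle``: interior angles of the
  shoulders-hips quadrilateral at the right shoulder / right hip.
- ``rt_faceAngle``: planar angle at the nose between the ray to the right ear
  and the ray to the shoulder midpoint (monotone in camera yaw).
- ``rt_trunksize``: |cross2d(shoulderR->shoulderL, shoulderR->hipR)| divided
  by the squared planar right-trunk length.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .errors import DegenerateGeometryError
from .geometry import Vec, angle_between, length_ratio, trunk_size
from .landmarks import LandmarkFrame, vec

__all__ = [
    "FEATURE_NAMES",
    "ANGLE_FEATURES",
    "RATIO_FEATURES",
    "STAGE1_FEATURES",
    "STAGE2_FEATURES",
    "STAGE3_BASE_FEATURES",
    "CAM_ANGLE_FEATURE",
    "compute_features",
    "features_table",
]

FEATURE_NAMES: tuple[str, ...] = (
    "rtarm_distratio",
    "ltarm_distratio",
    "rtelbowhip_distratio",
    "ltelbowhip_distratio",
    "rthip_distratio",
    "lthip_distratio",
    "rtshoulder_distratio",
    "ltshoulder_distratio",
    "rtshoulderAbduction",
    "ltshoulderAbduction",
    "rtshoulder_3Dabduction",
    "ltshoulder_3Dabduction",
    "rtshoulderAngle",
    "ltshoulderAngle",
    "rtshoulder_3Dangle",
    "ltshoulder_3Dangle",
    "rt_uppertrunkAngle",
    "lt_uppertrunkAngle",
    "rt_lowertrunkAngle",
    "lt_lowertrunkAngle",
    "rt_faceAngle",
    "lt_faceAngle",
    "rt_trunksize",
    "lt_trunksize",
)

ANGLE_FEATURES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if "Angle" in n or "bduction" in n
)
RATIO_FEATURES: tuple[str, ...] = tuple(n for n in FEATURE_NAMES if "distratio" in n)

CAM_ANGLE_FEATURE = "estimate_camAngle"

# Feature subsets per model stage.
STAGE1_FEATURES: tuple[str, ...] = (
    "rtarm_distratio",
    "rtelbowhip_distratio",
    "rthip_distratio",
    "rtshoulder_distratio",
    "rtshoulderAbduction",
    "rtshoulder_3Dabduction",
    "rtshoulderAngle",
    "rtshoulder_3Dangle",
)
STAGE2_FEATURES: tuple[str, ...] = (
    "rthip_distratio",
    "lthip_distratio",
    "rt_uppertrunkAngle",
    "lt_uppertrunkAngle",
    "rt_lowertrunkAngle",
    "lt_lowertrunkAngle",
    "rt_faceAngle",
    "lt_faceAngle",
    "rt_trunksize",
    "lt_trunksize",
)
# The any-camera abduction model sees the right-arm geometry plus the
# estimated camera angle filled in by the camera model.
STAGE3_BASE_FEATURES: tuple[str, ...] = (
    "rtarm_distratio",
    "rtelbowhip_distratio",
    "rtshoulderAbduction",
    "rtshoulder_3Dabduction",
    "rtshoulderAngle",
    "rtshoulder_3Dangle",
)

LABEL_COLUMNS: tuple[str, ...] = ("true_abduction_deg", "camera_yaw_deg")
META_COLUMNS: tuple[str, ...] = ("subject_id", "frame_index")


def _named(feature: str, fn, *args, **kwargs) -> float:
    try:
        return fn(*args, **kwargs)
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(f"feature {feature!r}: {exc}") from exc


def _midpoint_vec(frame: LandmarkFrame, pair_a, pair_b) -> Vec:
    """Vector from the midpoint of two keypoints to the midpoint of two others."""
    a1, a2 = (frame[k] for k in pair_a)
    b1, b2 = (frame[k] for k in pair_b)
    return Vec(
        (b1.x + b2.x - a1.x - a2.x) / 2.0,
        (b1.y + b2.y - a1.y - a2.y) / 2.0,
        (b1.z + b2.z - a1.z - a2.z) / 2.0,
    )


def compute_features(frame: LandmarkFrame) -> dict[str, float]:
    """Compute the full named feature row for one frame.

    Raises
    ------
    MissingLandmarkError
        if a required keypoint is absent.
    DegenerateGeometryError
        if a ratio or angle is undefined; the message names the feature.
    """
    v = lambda a, b: vec(frame, a, b)  # noqa: E731

    arm_r = v("right_shoulder", "right_elbow")
    arm_l = v("left_shoulder", "left_elbow")
    trunk_r = v("right_shoulder", "right_hip")
    trunk_l = v("left_shoulder", "left_hip")
    elbowhip_r = v("right_elbow", "right_hip")
    elbowhip_l = v("left_elbow", "left_hip")
    hips_rl = v("right_hip", "left_hip")
    shoulders_rl = v("right_shoulder", "left_shoulder")
    # Downward trunk midline: shoulder midpoint -> hip midpoint.
    midline = _midpoint_vec(
        frame, ("right_shoulder", "left_shoulder"), ("right_hip", "left_hip")
    )
    face_r = v("nose", "right_ear")
    face_l = v("nose", "left_ear")
    nose_to_midshoulder = _midpoint_vec(
        frame, ("nose", "nose"), ("right_shoulder", "left_shoulder")
    )

    row: dict[str, float] = {}
    row["rtarm_distratio"] = _named("rtarm_distratio", length_ratio, arm_r, trunk_r)
    row["ltarm_distratio"] = _named("ltarm_distratio", length_ratio, arm_l, trunk_l)
    row["rtelbowhip_distratio"] = _named(
        "rtelbowhip_distratio", length_ratio, elbowhip_r, trunk_r
    )
    row["ltelbowhip_distratio"] = _named(
        "ltelbowhip_distratio", length_ratio, elbowhip_l, trunk_l
    )
    row["rthip_distratio"] = _named("rthip_distratio", length_ratio, trunk_r, hips_rl)
    row["lthip_distratio"] = _named("lthip_distratio", length_ratio, trunk_l, hips_rl)
    row["rtshoulder_distratio"] = _named(
        "rtshoulder_distratio", length_ratio, shoulders_rl, trunk_r
    )
    row["ltshoulder_distratio"] = _named(
        "ltshoulder_distratio", length_ratio, shoulders_rl, trunk_l
    )
    row["rtshoulderAbduction"] = _named(
        "rtshoulderAbduction", angle_between, arm_r, midline, "planar2d"
    )
    row["ltshoulderAbduction"] = _named(
        "ltshoulderAbduction", angle_between, arm_l, midline, "planar2d"
    )
    row["rtshoulder_3Dabduction"] = _named(
        "rtshoulder_3Dabduction", angle_between, arm_r, midline, "full3d"
    )
    row["ltshoulder_3Dabduction"] = _named(
        "ltshoulder_3Dabduction", angle_between, arm_l, midline, "full3d"
    )
    row["rtshoulderAngle"] = _named(
        "rtshoulderAngle", angle_between, arm_r, trunk_r, "planar2d"
    )
    row["ltshoulderAngle"] = _named(
        "ltshoulderAngle", angle_between, arm_l, trunk_l, "planar2d"
    )
    row["rtshoulder_3Dangle"] = _named(
        "rtshoulder_3Dangle", angle_between, arm_r, trunk_r, "full3d"
    )
    row["ltshoulder_3Dangle"] = _named(
        "ltshoulder_3Dangle", angle_between, arm_l, trunk_l, "full3d"
    )
    row["rt_uppertrunkAngle"] = _named(
        "rt_uppertrunkAngle", angle_between, shoulders_rl, trunk_r, "planar2d"
    )
    row["lt_uppertrunkAngle"] = _named(
        "lt_uppertrunkAngle", angle_between, -shoulders_rl, trunk_l, "planar2d"
    )
    row["rt_lowertrunkAngle"] = _named(
        "rt_lowertrunkAngle", angle_between, hips_rl, -trunk_r, "planar2d"
    )
    row["lt_lowertrunkAngle"] = _named(
        "lt_lowertrunkAngle", angle_between, -hips_rl, -trunk_l, "planar2d"
    )
    row["rt_faceAngle"] = _named(
        "rt_faceAngle", angle_between, face_r, nose_to_midshoulder, "planar2d"
    )
    row["lt_faceAngle"] = _named(
        "lt_faceAngle", angle_between, face_l, nose_to_midshoulder, "planar2d"
    )
    row["rt_trunksize"] = _named("rt_trunksize", trunk_size, shoulders_rl, trunk_r)
    row["lt_trunksize"] = _named("lt_trunksize", trunk_size, shoulders_rl, trunk_l)
    return row


def features_table(frames: Iterable[LandmarkFrame]) -> pd.DataFrame:
    """Feature rows for a frame collection, with metadata and label columns.

    Columns: subject_id, frame_index, the features in ``FEATURE_NAMES`` order,
    then true_abduction_deg and camera_yaw_deg (NaN where unlabeled).
    """
    records = []
    for frame in frames:
        row = {
            "subject_id": frame.subject_id,
            "frame_index": frame.frame_index,
        }
        row.update(compute_features(frame))
        row["true_abduction_deg"] = (
            float("nan")
            if frame.true_abduction_deg is None
            else frame.true_abduction_deg
        )
        row["camera_yaw_deg"] = (
            float("nan") if frame.camera_yaw_deg is None else frame.camera_yaw_deg
        )
        records.append(row)
    columns = list(META_COLUMNS) + list(FEATURE_NAMES) + list(LABEL_COLUMNS)
    return pd.DataFrame.from_records(records, columns=columns)


def stage3_features(mode: str = "table1") -> tuple[str, ...]:
    """Feature list for the any-camera abduction model.

    ``table1`` uses the right-arm geometry block; ``all-bilateral`` adds every
    bilateral feature (the variant in which all parameters feed the model).
    Both include ``estimate_camAngle``.
    """
    if mode == "table1":
        return STAGE3_BASE_FEATURES + (CAM_ANGLE_FEATURE,)
    if mode == "all-bilateral":
        return FEATURE_NAMES + (CAM_ANGLE_FEATURE,)
    raise ValueError(f"unknown stage-3 feature mode {mode!r}")
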