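"""Landmark data model: named pose keypoints grouped into frames.

Coordinates follow the convention of BlazePose-style pose estimators:
x grows to the image right, y grows downward, and z is an estimated depth
(smaller = closer to the camera), all re-centered on the mid-hip point so the
hip center sits at the origin of every frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .errors import MissingLandmarkError, ValidationError
from .geometry import Vec

# The subset of the 33 BlazePose keypoints this package consumes.
REQUIRED_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_hip",
    "right_hip",
)


@dataclass(frozen=True)
class Landmark:
    """One named keypoint with hip-centered normalized coordinates."""

    name: str
    x: float
    y: float
    z: float = 0.0

    def __post_init__(self):
        for c in (self.x, self.y, self.z):
            if not (isinstance(c, (int, float)) and math.isfinite(c)):
                raise ValidationError(
                    f"landmark {self.name!r} has non-finite coordinate {c!r}"
                )


@dataclass(frozen=True)
class LandmarkFrame:
    """All keypoints of one video frame, plus optional ground-truth labels.

    ``true_abduction_deg`` is the goniometer-style ground truth of the right
    shoulder abduction angle; ``camera_yaw_deg`` is the horizontal camera
    installation angle (0 = frontal, positive = to the subject's right).
    """

    landmarks: Mapping[str, Landmark]
    subject_id: str = "unknown"
    frame_index: int = 0
    true_abduction_deg: float | None = None
    camera_yaw_deg: float | None = None

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValidationError("frame_index must be non-negative")
        for kp in REQUIRED_KEYPOINTS:
            if kp not in self.landmarks:
                raise MissingLandmarkError(
                    kp, f"subject {self.subject_id} frame {self.frame_index}"
                )
        if self.true_abduction_deg is not None and not (
            0.0 <= self.true_abduction_deg <= 180.0
        ):
            raise ValidationError(
                f"true_abduction_deg {self.true_abduction_deg} outside [0, 180]"
            )

    def __getitem__(self, keypoint: str) -> Landmark:
        try:
            return self.landmarks[keypoint]
        except KeyError:
            raise MissingLandmarkError(
                keypoint, f"subject {self.subject_id} frame {self.frame_index}"
            ) from None

    def translated(self, dx: float, dy: float, dz: float = 0.0) -> "LandmarkFrame":
        """Return a copy with every landmark shifted by a constant offset."""
        moved = {
            k: replace(lm, x=lm.x + dx, y=lm.y + dy, z=lm.z + dz)
            for k, lm in self.landmarks.items()
        }
        return replace(self, landmarks=moved)

    def scaled(self, k: float) -> "LandmarkFrame":
        """Return a copy with every coordinate multiplied by ``k`` (k > 0)."""
        if k <= 0:
            raise ValidationError("scale factor must be positive")
        moved = {
            name: replace(lm, x=lm.x * k, y=lm.y * k, z=lm.z * k)
            for name, lm in self.landmarks.items()
        }
        return replace(self, landmarks=moved)


def vec(frame: LandmarkFrame, from_kp: str, to_kp: str) -> Vec:
    """Displacement vector from one keypoint to another (to - from)."""
    a = frame[from_kp]
    b = frame[to_kp]
    return Vec(b.x - a.x, b.y - a.y, b.z - a.z)


def frame_from_points(
    points: Mapping[str, Iterable[float]],
    subject_id: str = "unknown",
    frame_index: int = 0,
    true_abduction_deg: float | None = None,
    camera_yaw_deg: float | None = None,
) -> LandmarkFrame:
    """Build a frame from a mapping of keypoint name -> (x, y, z) triples."""
    lms = {}
    for name, xyz in points.items():
        x, y, z = (float(c) for c in xyz)
        lms[name] = Landmark(name, x, y, z)
    return LandmarkFrame(
        landmarks=lms,
        subject_id=subject_id,
        frame_index=frame_index,
        true_abduction_deg=true_abduction_deg,
        camera_yaw_deg=camera_yaw_deg,
    )
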