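"""Vector primitives for landmark geometry.

All angle computations return degrees in [0, 180].  2D ("planar") variants use
only the image-plane components (x, y) of a vector; 3D variants include the
estimated depth.  The cosine fed to ``acos`` is clamped to [-1, 1] so that
numerically (anti)parallel vectors never produce NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "Vec",
    "length",
    "length2d",
    "length_ratio",
    "angle_between",
    "cross2d",
    "triangle_area",
    "trunk_size",
]


@dataclass(frozen=True)
class Vec:
    """Displacement between two landmarks, in hip-centered normalized units."""

    dx: float
    dy: float
    dz: float = 0.0

    def __post_init__(self):
        for c in (self.dx, self.dy, self.dz):
            if not math.isfinite(c):
                raise ValidationError(f"non-finite vector component: {c!r}")

    def __neg__(self) -> "Vec":
        return Vec(-self.dx, -self.dy, -self.dz)


def length(v: Vec) -> float:
    """Euclidean length using all three components."""
    return math.sqrt(v.dx * v.dx + v.dy * v.dy + v.dz * v.dz)


def length2d(v: Vec) -> float:
    """Euclidean length in the image plane (z ignored)."""
    return math.hypot(v.dx, v.dy)


def length_ratio(a: Vec, b: Vec) -> float:
    """|a| / |b|; the denominator must be nonzero."""
    nb = length(b)
    if nb == 0.0:
        raise DegenerateGeometryError("length ratio denominator has zero length")
    return length(a) / nb


def angle_between(a: Vec, b: Vec, mode: str = "full3d") -> float:
    """Angle between two vectors in degrees, in [0, 180].

    Parameters
    ----------
    mode:
        ``"planar2d"`` uses only (dx, dy); ``"full3d"`` uses all components.
    """
    if mode == "planar2d":
        ax, ay, az = a.dx, a.dy, 0.0
        bx, by, bz = b.dx, b.dy, 0.0
    elif mode == "full3d":
        ax, ay, az = a.dx, a.dy, a.dz
        bx, by, bz = b.dx, b.dy, b.dz
    else:
        raise ValidationError(f"unknown angle mode {mode!r}")
    na = math.sqrt(ax * ax + ay * ay + az * az)
    nb = math.sqrt(bx * bx + by * by + bz * bz)
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError(
            f"angle undefined: zero-length vector in mode {mode!r}"
        )
    cos = (ax * bx + ay * by + az * bz) / (na * nb)
    cos = max(-1.0, min(1.0, cos))
    return math.degrees(math.acos(cos))


def cross2d(a: Vec, b: Vec) -> float:
    """Signed z-component of the planar cross product, ax*by - ay*bx."""
    return a.dx * b.dy - a.dy * b.dx


def triangle_area(a: Vec, b: Vec) -> float:
    """Area of the triangle spanned by two planar vectors: 0.5 * |ax*by - ay*bx|."""
    return 0.5 * abs(cross2d(a, b))


def trunk_size(shoulder_vec: Vec, trunk_vec: Vec) -> float:
    """Scale-free trunk area: |cross2d(shoulder, trunk)| / |trunk|_2d^2.

    Numerator and denominator are both quadratic in the coordinates, so the
    value is invariant under uniform scaling of the whole frame.
    """
    nt = length2d(trunk_vec)
    if nt == 0.0:
        raise DegenerateGeometryError("trunk size undefined: zero trunk length")
    return abs(cross2d(shoulder_vec, trunk_vec)) / (nt * nt)
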