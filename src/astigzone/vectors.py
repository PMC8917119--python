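"""Double-angle vector algebra for astigmatism.

An astigmatism of magnitude ``C`` at steep axis ``theta`` (degrees) maps to
the Cartesian point ``(C*cos(2*theta), C*sin(2*theta))``.  Doubling the angle
makes physically opposite meridians (0 and 180) coincide, so astigmatism
vectors add, subtract and average like ordinary 2-D vectors.  All cohort-level
statistics in this package are computed in this doubled-angle plane; results
are mapped back to magnitude @ axis for reporting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .types import KeratometryReading, PolarAstigmatism, normalize_axis


@dataclass(frozen=True)
class DoubleAngleVector:
    """Cartesian (x, y) representation of astigmatism in doubled-angle space."""

    x: float
    y: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.x, self.y)

    def __add__(self, other: "DoubleAngleVector") -> "DoubleAngleVector":
        return DoubleAngleVector(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "DoubleAngleVector") -> "DoubleAngleVector":
        return DoubleAngleVector(self.x - other.x, self.y - other.y)

    def __neg__(self) -> "DoubleAngleVector":
        return DoubleAngleVector(-self.x, -self.y)


class AstigmatismType(str, enum.Enum):
    """Steep-meridian orientation class."""

    WTR = "WTR"
    ATR = "ATR"
    OBLIQUE = "OBLIQUE"


def to_double_angle(a: PolarAstigmatism) -> DoubleAngleVector:
    """Map magnitude @ axis to (C cos 2θ, C sin 2θ); magnitude is preserved."""
    t = math.radians(2.0 * a.axis)
    return DoubleAngleVector(a.magnitude * math.cos(t), a.magnitude * math.sin(t))


def from_double_angle(v: DoubleAngleVector) -> PolarAstigmatism:
    """Inverse map; (0, 0) yields the canonical zero astigmatism 0 D @ 0."""
    mag = v.magnitude
    if mag == 0.0:
        return PolarAstigmatism(0.0, 0.0)
    axis = math.degrees(math.atan2(v.y, v.x)) / 2.0
    return PolarAstigmatism(mag, normalize_axis(axis))


def mirror_left_eye(a: PolarAstigmatism) -> PolarAstigmatism:
    """Reflect a left-eye axis into right-eye orientation: axis -> 180 − axis.

    Left and right eyes are mirror images about the vertical midline, so a
    left eye's nasal-temporal meridians are flipped relative to a right eye's.
    Applying this involution before pooling keeps oblique axes from the two
    eyes from cancelling artificially.  Magnitude is unchanged.
    """
    return PolarAstigmatism(a.magnitude, normalize_axis(180.0 - a.axis))


def keratometric_astigmatism(k: KeratometryReading) -> PolarAstigmatism:
    """Corneal astigmatism from a keratometry reading: steep − flat @ steep axis."""
    return PolarAstigmatism(k.steep_k - k.flat_k, k.steep_axis)


def classify_astigmatism(axis: float) -> AstigmatismType:
    """Classify a steep-meridian axis as WTR, ATR or oblique.

    WTR is the closed band [60, 120] (steep meridian near vertical), ATR is
    [0, 30) ∪ (150, 180) (near horizontal), and the remaining axes
    [30, 60) ∪ (120, 150] are oblique.  The shared endpoints 30/60/120/150 are
    resolved deterministically: WTR keeps both its endpoints (clinical
    convention centres WTR on 90), so 60 and 120 are WTR while 30 and 150 fall
    to oblique.  Every axis in [0, 180) receives exactly one label.
    """
    if not (0.0 <= axis < 180.0):
        raise ValueError(f"axis must lie in [0, 180), got {axis}")
    if 60.0 <= axis <= 120.0:
        return AstigmatismType.WTR
    if axis < 30.0 or axis > 150.0:
        return AstigmatismType.ATR
    return AstigmatismType.OBLIQUE


def classify_polar(a: PolarAstigmatism) -> tuple[AstigmatismType, bool]:
    """Classify a polar astigmatism; flag the physically meaningless zero vector.

    A zero-magnitude astigmatism has no steep meridian; its canonical axis 0
    classifies as ATR, but the second element is True so that reports can
    exclude such eyes from subtype tallies.
    """
    return classify_astigmatism(a.axis), a.magnitude == 0.0


def vector_add(a: DoubleAngleVector, b: DoubleAngleVector) -> DoubleAngleVector:
    return a + b


def vector_subtract(a: DoubleAngleVector, b: DoubleAngleVector) -> DoubleAngleVector:
    return a - b
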