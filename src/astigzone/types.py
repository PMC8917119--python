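"""Core domain types for the dual-zone astigmatism analysis.

Clinical conventions used throughout:

* Astigmatism axes are degrees in ``[0, 180)``; an axis of 180 is the same
  meridian as 0 and is canonicalised to 0.
* Refractions are stored internally in minus-cylinder form (``cylinder <= 0``);
  plus-cylinder input is transposed on construction.
* Keratometry readings are taken at one of two mire-ring diameter zones,
  2.4 mm or 3.3 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

ZONES = (2.4, 3.3)

OD = "OD"
OS = "OS"


def normalize_axis(axis: float) -> float:
    """Map an axis in degrees onto the canonical half-open range [0, 180)."""
    a = float(axis) % 180.0
    # guard against -1e-16 % 180 -> 179.999... style artefacts
    if a >= 180.0 or abs(a - 180.0) < 1e-12:
        a = 0.0
    return a


@dataclass(frozen=True)
class PolarAstigmatism:
    """Astigmatism as magnitude (D) at a steep-meridian axis (degrees).

    The clinical representation: a cylinder power and the meridian along
    which the cornea (or refraction) is steepest.  Zero magnitude has the
    canonical axis 0.
    """

    magnitude: float
    axis: float

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError(f"astigmatism magnitude must be >= 0, got {self.magnitude}")
        axis = normalize_axis(self.axis) if self.magnitude > 0 else 0.0
        object.__setattr__(self, "magnitude", float(self.magnitude))
        object.__setattr__(self, "axis", axis)


@dataclass(frozen=True)
class KeratometryReading:
    """Principal-meridian corneal powers at one measurement zone.

    ``steep_axis`` is the meridian of ``steep_k``.  ``zone`` is the mire-ring
    diameter in millimetres (2.4 or 3.3 for the biometer modelled here).
    """

    flat_k: float
    steep_k: float
    steep_axis: float
    zone: float

    def __post_init__(self) -> None:
        if self.steep_k < self.flat_k - 1e-9:
            raise ValueError(
                f"steep K ({self.steep_k}) must be >= flat K ({self.flat_k})"
            )
        if float(self.zone) not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}, got {self.zone}")
        object.__setattr__(self, "flat_k", float(self.flat_k))
        object.__setattr__(self, "steep_k", float(max(self.steep_k, self.flat_k)))
        object.__setattr__(self, "steep_axis", normalize_axis(self.steep_axis))
        object.__setattr__(self, "zone", float(self.zone))

    @property
    def average_k(self) -> float:
        """Mean corneal power over the two principal meridians (D)."""
        return 0.5 * (self.flat_k + self.steep_k)

    @property
    def cylinder(self) -> float:
        """Keratometric cylinder magnitude steep − flat (D, >= 0)."""
        return self.steep_k - self.flat_k


@dataclass(frozen=True)
class SpheroCylinder:
    """A sphero-cylindrical refraction, canonicalised to minus-cylinder form.

    In minus-cylinder notation the recorded axis marks the *flat* meridian;
    the steep meridian lies 90 degrees away.  Plus-cylinder input is
    transposed on construction (sphere += cyl, axis += 90, cyl = -cyl).
    """

    sphere: float
    cylinder: float
    axis: float

    def __post_init__(self) -> None:
        sphere, cylinder, axis = float(self.sphere), float(self.cylinder), float(self.axis)
        if cylinder > 0:
            sphere += cylinder
            cylinder = -cylinder
            axis += 90.0
        object.__setattr__(self, "sphere", sphere)
        object.__setattr__(self, "cylinder", cylinder)
        object.__setattr__(self, "axis", normalize_axis(axis) if cylinder != 0 else normalize_axis(axis))

    @property
    def principal_powers(self) -> tuple[float, float]:
        """Powers along the two principal meridians: (sphere, sphere+cylinder)."""
        return self.sphere, self.sphere + self.cylinder

    @property
    def spherical_equivalent(self) -> float:
        return self.sphere + 0.5 * self.cylinder


@dataclass(frozen=True)
class EyeRecord:
    """One eye's biometric, keratometric and refractive data: a cohort row."""

    patient_id: str
    eye_id: str
    laterality: str
    age: float
    sex: str
    axial_length: float
    iol_power: float
    preop_k: Mapping[float, KeratometryReading]
    postop_k: Mapping[float, KeratometryReading]
    postop_refraction: SpheroCylinder
    corneal_irregularity: Optional[float] = None
    postop_bcva_decimal: Optional[float] = None
    prior_refractive_surgery: Optional[bool] = None
    complication: Optional[bool] = None
    corneal_opacity: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.laterality not in (OD, OS):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if not (0.0 < self.age < 120.0):
            raise ValueError(f"age out of range (0, 120): {self.age}")
        if not (15.0 < self.axial_length < 40.0):
            raise ValueError(f"axial length out of range (15, 40): {self.axial_length}")
        pre = dict(self.preop_k)
        post = dict(self.postop_k)
        if not pre or set(pre) != set(post):
            raise ValueError(
                f"eye {self.eye_id}: preop and postop keratometry must cover the "
                f"same non-empty zone set (got {sorted(pre)} vs {sorted(post)})"
            )
        for zone, reading in {**pre, **post}.items():
            if float(zone) != reading.zone:
                raise ValueError(
                    f"eye {self.eye_id}: reading zone {reading.zone} filed under key {zone}"
                )
        object.__setattr__(self, "preop_k", pre)
        object.__setattr__(self, "postop_k", post)

    @property
    def zones(self) -> tuple[float, ...]:
        return tuple(sorted(self.preop_k))

    def keratometry(self, epoch: str, zone: float) -> KeratometryReading:
        """Return the reading for ``epoch`` in {'preop', 'postop'} at ``zone``."""
        table = self.preop_k if epoch == "preop" else self.postop_k
        try:
            return table[float(zone)]
        except KeyError:
            raise KeyError(
                f"eye {self.eye_id}: no {epoch} keratometry at the {zone}-mm zone"
            ) from None


@dataclass
class Cohort:
    """An ordered collection of eyes plus free-text provenance."""

    eyes: list[EyeRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [e.eye_id for e in self.eyes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate eye_ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.eyes)

    def __iter__(self) -> Iterable[EyeRecord]:
        return iter(self.eyes)

    @property
    def zones(self) -> tuple[float, ...]:
        """Zones present in every eye of the cohort."""
        if not self.eyes:
            return ()
        common = set(self.eyes[0].zones)
        for e in self.eyes[1:]:
            common &= set(e.zones)
        return tuple(sorted(common))
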