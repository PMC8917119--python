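"""Read and write the flat per-eye cohort CSV and apply inclusion filters.

The on-disk format is one row per eye with zone-suffixed keratometry columns
(``preop_flat_k_24`` ... ``postop_steep_axis_33``); the machine-readable data
dictionary ships with the package (``astigzone/data/cohort_schema.json``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .types import Cohort, EyeRecord, KeratometryReading, SpheroCylinder

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "patient_id", "eye_id", "laterality", "age", "sex", "axial_length",
    "iol_power", "ref_sphere", "ref_cylinder", "ref_axis",
)

_ZONE_SUFFIX = {2.4: "24", 3.3: "33"}
_OPTIONAL_FLOAT = ("corneal_irregularity", "bcva_decimal")
_OPTIONAL_BOOL = ("prior_refractive_surgery", "complication", "corneal_opacity")


class SchemaError(ValueError):
    """The file header does not match the documented column schema."""


@dataclass(frozen=True)
class CsvDialect:
    """Reader options: which cylinder sign convention the file uses."""

    cylinder_convention: str = "minus"  # "minus" | "plus"

    def __post_init__(self) -> None:
        if self.cylinder_convention not in ("minus", "plus"):
            raise ValueError(
                f"cylinder_convention must be 'minus' or 'plus', "
                f"got {self.cylinder_convention!r}"
            )


@dataclass(frozen=True)
class RejectedRow:
    """A row that failed parsing or invariant checks, with the reason."""

    row_index: int
    eye_id: str
    reason: str


def column_schema() -> dict:
    """Return the shipped data dictionary describing the cohort CSV."""
    text = resources.files("astigzone").joinpath("data/cohort_schema.json").read_text()
    return json.loads(text)


def _zone_columns(zone: float, epoch: str) -> tuple[str, str, str]:
    s = _ZONE_SUFFIX[zone]
    return (f"{epoch}_flat_k_{s}", f"{epoch}_steep_k_{s}", f"{epoch}_steep_axis_{s}")


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    s = str(value).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def _parse_row(row: pd.Series, zones: list[float], dialect: CsvDialect) -> EyeRecord:
    def num(col: str) -> float:
        v = row[col]
        if pd.isna(v) or v == "":
            raise ValueError(f"missing value in column {col!r}")
        return float(v)

    def opt(col: str) -> Optional[float]:
        if col not in row.index:
            return None
        v = row[col]
        if pd.isna(v) or v == "":
            return None
        return float(v)

    preop, postop = {}, {}
    for zone in zones:
        for epoch, table in (("preop", preop), ("postop", postop)):
            fcol, scol, acol = _zone_columns(zone, epoch)
            table[zone] = KeratometryReading(
                flat_k=num(fcol), steep_k=num(scol), steep_axis=num(acol), zone=zone
            )

    cyl = num("ref_cylinder")
    if dialect.cylinder_convention == "minus" and cyl > 0:
        raise ValueError(
            f"positive cylinder {cyl} in a minus-cylinder file; "
            "declare cylinder_convention='plus' in the dialect if intended"
        )
    refraction = SpheroCylinder(num("ref_sphere"), cyl, num("ref_axis"))

    flags = {col: _parse_bool(row[col]) if col in row.index else None
             for col in _OPTIONAL_BOOL}

    return EyeRecord(
        patient_id=str(row["patient_id"]),
        eye_id=str(row["eye_id"]),
        laterality=str(row["laterality"]).strip(),
        age=num("age"),
        sex=str(row["sex"]).strip(),
        axial_length=num("axial_length"),
        iol_power=num("iol_power"),
        preop_k=preop,
        postop_k=postop,
        postop_refraction=refraction,
        corneal_irregularity=opt("corneal_irregularity"),
        postop_bcva_decimal=opt("bcva_decimal"),
        **flags,
    )


def read_cohort(
    path: str | Path, dialect: CsvDialect = CsvDialect()
) -> tuple[Cohort, list[RejectedRow]]:
    """Read a cohort CSV.

    Returns the cohort of all parseable rows together with a rejects report:
    rows violating numeric parsing or domain invariants (e.g. steep K below
    flat K) are collected with a reason, never silently dropped.  A missing
    mandatory column raises :class:`SchemaError` naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    zones = []
    for zone in _ZONE_SUFFIX:
        cols = _zone_columns(zone, "preop") + _zone_columns(zone, "postop")
        present = [c in df.columns for c in cols]
        if all(present):
            zones.append(zone)
        elif any(present):
            absent = [c for c, p in zip(cols, present) if not p]
            raise SchemaError(
                f"incomplete {zone}-mm keratometry block: missing {', '.join(absent)}"
            )
    if not zones:
        raise SchemaError("no complete keratometry zone block found in header")

    eyes: list[EyeRecord] = []
    rejects: list[RejectedRow] = []
    for idx, row in df.iterrows():
        eye_id = str(row.get("eye_id", f"<row {idx}>"))
        try:
            eyes.append(_parse_row(row, zones, dialect))
        except (ValueError, KeyError) as exc:
            rejects.append(RejectedRow(int(idx), eye_id, str(exc)))

    cohort = Cohort(eyes=eyes, provenance=f"read from {path}")
    if rejects:
        logger.warning("%d row(s) rejected while reading %s", len(rejects), path)
    return cohort, rejects


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV (minus-cylinder convention, 6-decimal numerics).

    ``write_cohort`` followed by :func:`read_cohort` reproduces every numeric
    field to the stated precision.
    """
    path = Path(path)
    zones = cohort.zones if cohort.eyes else tuple(_ZONE_SUFFIX)

    def fmt(v: Optional[float]) -> str:
        return "" if v is None else f"{v:.6f}"

    def fmtb(v: Optional[bool]) -> str:
        return "" if v is None else str(int(v))

    rows = []
    for eye in cohort:
        row: dict[str, str] = {
            "patient_id": eye.patient_id,
            "eye_id": eye.eye_id,
            "laterality": eye.laterality,
            "age": fmt(eye.age),
            "sex": eye.sex,
            "axial_length": fmt(eye.axial_length),
            "iol_power": fmt(eye.iol_power),
        }
        for zone in zones:
            for epoch in ("preop", "postop"):
                k = eye.keratometry(epoch, zone)
                fcol, scol, acol = _zone_columns(zone, epoch)
                row[fcol], row[scol], row[acol] = fmt(k.flat_k), fmt(k.steep_k), fmt(k.steep_axis)
        r = eye.postop_refraction
        row["ref_sphere"], row["ref_cylinder"], row["ref_axis"] = fmt(r.sphere), fmt(r.cylinder), fmt(r.axis)
        row["corneal_irregularity"] = fmt(eye.corneal_irregularity)
        row["bcva_decimal"] = fmt(eye.postop_bcva_decimal)
        row["prior_refractive_surgery"] = fmtb(eye.prior_refractive_surgery)
        row["complication"] = fmtb(eye.complication)
        row["corneal_opacity"] = fmtb(eye.corneal_opacity)
        rows.append(row)

    header = list(MANDATORY_COLUMNS[:7])
    for zone in zones:
        for epoch in ("preop", "postop"):
            header.extend(_zone_columns(zone, epoch))
    header += ["ref_sphere", "ref_cylinder", "ref_axis"]
    header += list(_OPTIONAL_FLOAT) + list(_OPTIONAL_BOOL)

    pd.DataFrame(rows, columns=header).to_csv(path, index=False)


@dataclass(frozen=True)
class InclusionCriteria:
    """Row-level inclusion rules applied before analysis.

    The default BCVA floor encodes the 20/30-or-better requirement as decimal
    acuity >= 0.67 (Snellen fraction 20/30 rounded to two decimals).
    """

    bcva_floor: float = 0.67
    exclude_prior_refractive_surgery: bool = True
    exclude_complications: bool = True
    exclude_corneal_opacity: bool = True


@dataclass
class FilterLog:
    """Per-rule exclusion counts plus the rules skipped for missing data."""

    excluded: dict[str, int] = field(default_factory=dict)
    skipped_rules: list[str] = field(default_factory=list)

    @property
    def total_excluded(self) -> int:
        return sum(self.excluded.values())


def apply_inclusion_filters(
    cohort: Cohort, criteria: InclusionCriteria = InclusionCriteria()
) -> tuple[Cohort, FilterLog]:
    """Filter a cohort by the inclusion rules; each excluded eye is counted
    under the first rule it fails.  A rule whose column is absent from every
    row is skipped and logged, never treated as passing silently.

    Invariant: ``len(filtered) + log.total_excluded == len(cohort)``.
    """
    log = FilterLog()
    rules: list[tuple[str, object]] = []
    if any(e.postop_bcva_decimal is not None for e in cohort):
        rules.append(("low_bcva", lambda e: (
            e.postop_bcva_decimal is not None and e.postop_bcva_decimal < criteria.bcva_floor
        )))
    else:
        log.skipped_rules.append("low_bcva")

    flag_rules = [
        ("prior_refractive_surgery", criteria.exclude_prior_refractive_surgery,
         lambda e: bool(e.prior_refractive_surgery)),
        ("complication", criteria.exclude_complications,
         lambda e: bool(e.complication)),
        ("corneal_opacity", criteria.exclude_corneal_opacity,
         lambda e: bool(e.corneal_opacity)),
    ]
    attr = {"prior_refractive_surgery": "prior_refractive_surgery",
            "complication": "complication", "corneal_opacity": "corneal_opacity"}
    for name, enabled, pred in flag_rules:
        if not enabled:
            continue
        if any(getattr(e, attr[name]) is not None for e in cohort):
            rules.append((name, pred))
        else:
            log.skipped_rules.append(name)

    for name, _ in rules:
        log.excluded[name] = 0

    kept = []
    for eye in cohort:
        for name, pred in rules:
            if pred(eye):
                log.excluded[name] += 1
                break
        else:
            kept.append(eye)

    filtered = Cohort(eyes=kept, provenance=cohort.provenance + " | inclusion-filtered")
    for name, n in log.excluded.items():
        logger.info("inclusion filter %s excluded %d eye(s)", name, n)
    for name in log.skipped_rules:
        logger.info("inclusion filter %s skipped (column absent)", name)
    return filtered, log
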