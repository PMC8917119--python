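"""Synthetic cohort generator with ground truth for recovery testing.

Emulates a retrospective cataract-surgery cohort measured with a dual-zone
optical biometer: per-eye demographics and biometrics from truncated
normals, a WTR/ATR/oblique subtype mixture with wrapped-normal axis scatter
in doubled-angle space, a systematic zone offset on mean keratometry
(the smaller mire ring reads slightly steeper), a systematic surgically
induced astigmatism oriented by the incision meridian, a configurable true
posterior-cornea model, and independent measurement/refraction noise.

Everything the generator knows but the analysis must estimate (true anterior
and posterior astigmatism, per-eye SIA, true total refractive astigmatism,
drawn subtype) goes into a :class:`GroundTruth` sidecar that the analysis
path never reads.

Draw order is fixed and documented (one eye at a time, fields in the order
listed in :func:`generate_cohort`), so a seed fully determines the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .prediction import (
    PcaModel,
    fixed_atr_pca,
    refraction_to_spectacle_plane,
)
from .types import Cohort, EyeRecord, KeratometryReading, PolarAstigmatism, SpheroCylinder
from .vectors import (
    AstigmatismType,
    DoubleAngleVector,
    classify_astigmatism,
    from_double_angle,
    mirror_left_eye,
    to_double_angle,
)

_SUBTYPES = (AstigmatismType.WTR, AstigmatismType.ATR, AstigmatismType.OBLIQUE)


def _zero_subtype_errors() -> dict[AstigmatismType, DoubleAngleVector]:
    return {t: DoubleAngleVector(0.0, 0.0) for t in _SUBTYPES}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort; defaults emulate the study cohort.

    Units: ages in years, lengths in mm, powers in D, axes/angles in degrees,
    vertex distance in metres.  Noise SDs apply per doubled-angle component.
    """

    n_eyes: int = 101
    seed: int = 0

    age_mean: float = 68.7
    age_sd: float = 9.3
    age_range: tuple[float, float] = (47.0, 89.0)
    axial_length_mean: float = 24.7
    axial_length_sd: float = 2.0
    axial_length_range: tuple[float, float] = (21.86, 30.25)
    iol_power_mean: float = 18.1
    iol_power_sd: float = 5.2
    iol_power_range: tuple[float, float] = (6.0, 27.5)
    male_fraction: float = 0.525
    os_fraction: float = 0.446

    subtype_weights: tuple[float, float, float] = (0.465, 0.327, 0.208)  # WTR, ATR, OBL
    ca_magnitude_mean: float = 0.7
    ca_magnitude_sd: float = 0.5
    ca_magnitude_range: tuple[float, float] = (0.05, 2.05)
    axis_sd_deg: float = 12.0  # wrapped-normal scatter of the axis about the subtype centre

    pca_true: PcaModel = field(default_factory=fixed_atr_pca)
    incision_axis: float = 145.0
    sia_mean_magnitude: float = 0.10
    sia_component_sd: float = 0.25

    flat_k_mean: float = 43.57
    flat_k_sd: float = 1.5
    zone_offset_preop: float = 0.04  # 2.4-mm mean K minus 3.3-mm mean K
    zone_offset_postop: float = 0.08
    postop_mean_k_shift: float = 0.12
    mean_k_noise_sd: float = 0.05
    k_noise_sd: float = 0.20
    refraction_noise_sd: float = 0.45
    sphere_noise_sd: float = 0.25

    vertex_distance: float = 0.012
    subtype_error: dict[AstigmatismType, DoubleAngleVector] = field(
        default_factory=_zero_subtype_errors
    )

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if abs(sum(self.subtype_weights) - 1.0) > 1e-9:
            raise ValueError(f"subtype_weights must sum to 1, got {self.subtype_weights}")
        for name in ("age_sd", "axial_length_sd", "iol_power_sd", "ca_magnitude_sd",
                     "axis_sd_deg", "sia_component_sd", "flat_k_sd", "mean_k_noise_sd",
                     "k_noise_sd", "refraction_noise_sd", "sphere_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.os_fraction <= 1.0 and 0.0 <= self.male_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def sia_mean(self) -> DoubleAngleVector:
        """Systematic SIA vector: the incision flattens its own meridian, so
        the induced steep axis sits 90 degrees from the incision."""
        steep_axis = (self.incision_axis - 90.0) % 180.0
        return to_double_angle(PolarAstigmatism(self.sia_mean_magnitude, steep_axis))

    def noiseless(self) -> "GeneratorConfig":
        """Copy with all measurement/refraction noise and SIA scatter zeroed."""
        return replace(
            self,
            sia_component_sd=0.0,
            mean_k_noise_sd=0.0,
            k_noise_sd=0.0,
            refraction_noise_sd=0.0,
            sphere_noise_sd=0.0,
        )


@dataclass
class GroundTruth:
    """Per-eye truth table; analysis code must never read it."""

    table: pd.DataFrame
    config: GeneratorConfig

    def labels(self) -> list[AstigmatismType]:
        return [AstigmatismType(s) for s in self.table["subtype"]]

    def sia_vectors(self) -> list[DoubleAngleVector]:
        return [DoubleAngleVector(x, y)
                for x, y in zip(self.table["sia_x"], self.table["sia_y"])]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.9f")


_SUBTYPE_CENTRES = {
    AstigmatismType.WTR: (90.0,),
    AstigmatismType.ATR: (0.0,),  # 0 and 180 are the same doubled-angle point
    AstigmatismType.OBLIQUE: (45.0, 135.0),
}


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _reading(avg_k: float, ca: PolarAstigmatism, zone: float) -> KeratometryReading:
    return KeratometryReading(
        flat_k=avg_k - ca.magnitude / 2.0,
        steep_k=avg_k + ca.magnitude / 2.0,
        steep_axis=ca.axis,
        zone=zone,
    )


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its ground truth, deterministically from the seed.

    Per eye, in order: (1) demographics and biometrics from truncated
    normals; (2) subtype by mixture weights, steep axis wrapped-normal about
    the subtype centre, magnitude truncated-normal — the true anterior
    corneal astigmatism; (3) true posterior astigmatism from ``pca_true``;
    (4) per-zone preoperative keratometry: mean K anchored per eye with the
    2.4-mm zone offset, astigmatism = truth plus doubled-space measurement
    noise; (5) true SIA about the systematic incision vector; postoperative
    anterior truth = preop ⊕ SIA; (6) per-zone postoperative keratometry with
    its own zone offset and noise; (7) manifest refraction from the true
    total astigmatism (anterior ⊕ posterior ⊕ subtype bias) plus refraction
    noise, expressed as a minus-cylinder sphero-cylinder at the spectacle
    plane via the inverse vertex transform; (8) left eyes have all stored
    axes mirrored (the analysis-side mirror undoes this).
    """
    rng = np.random.default_rng(config.seed)
    eyes: list[EyeRecord] = []
    truth_rows: list[dict] = []
    weights = np.asarray(config.subtype_weights, dtype=float)

    for i in range(config.n_eyes):
        eye_id = f"E{i + 1:04d}"
        patient_id = f"P{i + 1:04d}"

        age = _truncnorm(rng, config.age_mean, config.age_sd, *config.age_range)
        axial_length = _truncnorm(rng, config.axial_length_mean, config.axial_length_sd,
                                  *config.axial_length_range)
        iol_power = _truncnorm(rng, config.iol_power_mean, config.iol_power_sd,
                               *config.iol_power_range)
        sex = "M" if rng.random() < config.male_fraction else "F"
        laterality = "OS" if rng.random() < config.os_fraction else "OD"

        subtype = _SUBTYPES[int(rng.choice(3, p=weights))]
        centres = _SUBTYPE_CENTRES[subtype]
        centre = centres[int(rng.integers(len(centres)))] if len(centres) > 1 else centres[0]
        # wrapped normal on the doubled angle: 2*axis ~ N(2*centre, (2*sd)^2) mod 360
        doubled = (2.0 * centre + 2.0 * config.axis_sd_deg * rng.standard_normal()) % 360.0
        axis = doubled / 2.0
        magnitude = _truncnorm(rng, config.ca_magnitude_mean, config.ca_magnitude_sd,
                               *config.ca_magnitude_range)
        anterior_pre = PolarAstigmatism(magnitude, axis)
        # the axis scatter can cross a class boundary, so the eye's subtype
        # label (and any subtype-specific bias) follows the realised axis,
        # while the latent mixture component is kept for reference
        label = classify_astigmatism(anterior_pre.axis)

        posterior = config.pca_true.predict(anterior_pre)

        base_flat = config.flat_k_mean + config.flat_k_sd * rng.standard_normal()
        base_avg = base_flat + anterior_pre.magnitude / 2.0

        sia = DoubleAngleVector(
            config.sia_mean.x + config.sia_component_sd * rng.standard_normal(),
            config.sia_mean.y + config.sia_component_sd * rng.standard_normal(),
        )
        anterior_post = from_double_angle(to_double_angle(anterior_pre) + sia)

        readings: dict[str, dict[float, KeratometryReading]] = {"preop": {}, "postop": {}}
        for epoch, anterior_true, zone_offset, k_shift in (
            ("preop", anterior_pre, config.zone_offset_preop, 0.0),
            ("postop", anterior_post, config.zone_offset_postop, config.postop_mean_k_shift),
        ):
            for zone in (2.4, 3.3):
                offset = zone_offset if zone == 2.4 else 0.0
                avg = (base_avg + k_shift + offset
                       + config.mean_k_noise_sd * rng.standard_normal())
                noise = DoubleAngleVector(
                    config.k_noise_sd * rng.standard_normal(),
                    config.k_noise_sd * rng.standard_normal(),
                )
                measured = from_double_angle(to_double_angle(anterior_true) + noise)
                readings[epoch][zone] = _reading(avg, measured, zone)

        total_true = from_double_angle(
            to_double_angle(anterior_post)
            + to_double_angle(posterior)
            + config.subtype_error[label]
        )
        refr_noise = DoubleAngleVector(
            config.refraction_noise_sd * rng.standard_normal(),
            config.refraction_noise_sd * rng.standard_normal(),
        )
        observed = from_double_angle(to_double_angle(total_true) + refr_noise)
        se = config.sphere_noise_sd * rng.standard_normal()
        corneal = SpheroCylinder(
            sphere=se + observed.magnitude / 2.0,
            cylinder=-observed.magnitude,
            axis=(observed.axis + 90.0) % 180.0,
        )
        refraction = refraction_to_spectacle_plane(corneal, config.vertex_distance)

        if laterality == "OS":
            # store real-world (unmirrored) axes; the analysis mirror restores
            # the canonical right-eye orientation used for all truth fields
            for epoch in readings:
                for zone, k in readings[epoch].items():
                    mirrored = mirror_left_eye(PolarAstigmatism(k.cylinder, k.steep_axis))
                    readings[epoch][zone] = _reading(k.average_k, mirrored, zone)
            refraction = SpheroCylinder(
                refraction.sphere, refraction.cylinder, (180.0 - refraction.axis) % 180.0
            )

        bcva = float(np.round(rng.uniform(0.7, 1.2), 1))
        irregularity = float(abs(0.3 + 0.1 * rng.standard_normal()))

        eyes.append(EyeRecord(
            patient_id=patient_id,
            eye_id=eye_id,
            laterality=laterality,
            age=age,
            sex=sex,
            axial_length=axial_length,
            iol_power=iol_power,
            preop_k=readings["preop"],
            postop_k=readings["postop"],
            postop_refraction=refraction,
            corneal_irregularity=irregularity,
            postop_bcva_decimal=bcva,
        ))
        truth_rows.append({
            "eye_id": eye_id,
            "laterality": laterality,
            "subtype": label.value,
            "mixture_component": subtype.value,
            "anterior_preop_mag": anterior_pre.magnitude,
            "anterior_preop_axis": anterior_pre.axis,
            "posterior_mag": posterior.magnitude,
            "posterior_axis": posterior.axis,
            "sia_x": sia.x,
            "sia_y": sia.y,
            "total_x": to_double_angle(total_true).x,
            "total_y": to_double_angle(total_true).y,
        })

    provenance = f"synthetic cohort: seed={config.seed}, n={config.n_eyes}, pca_true={config.pca_true.name}"
    cohort = Cohort(eyes=eyes, provenance=provenance)
    truth = GroundTruth(table=pd.DataFrame(truth_rows), config=config)
    return cohort, truth


@dataclass(frozen=True)
class RecoveryReport:
    """How well the pipeline recovered the generator's known quantities."""

    n: int
    sia_bias_x: float            # estimated mean SIA minus configured systematic SIA
    sia_bias_y: float
    sia_se_x: float              # standard error of the estimated mean, per component
    sia_se_y: float
    subgroup_centroids: dict[AstigmatismType, tuple[float, float]]
    subgroup_expected: dict[AstigmatismType, tuple[float, float]]
    subgroup_counts_estimated: dict[AstigmatismType, int]
    subgroup_counts_truth: dict[AstigmatismType, int]


def recovery_report(
    cohort: Cohort,
    truth: GroundTruth,
    zone: float,
    pca: Optional[PcaModel] = None,
) -> RecoveryReport:
    """Compare pipeline estimates against the generator's ground truth.

    Estimates the mean SIA and per-subtype prediction-error centroids from
    the cohort alone (postop-keratometry path with ``pca``, defaulting to the
    generator's true model) and reports biases against the configured
    systematic SIA and injected subtype errors, with per-component standard
    errors for calibration checks.  Subtype counts are tallied both from the
    measured preoperative axes (as the analysis would) and from the drawn
    truth labels.
    """
    from .prediction import build_prediction_records, eye_anterior_ca, mean_sia, sia_vector

    if list(truth.table["eye_id"]) != [e.eye_id for e in cohort]:
        raise ValueError("cohort and truth tables do not list the same eyes in order")

    config = truth.config
    pca = pca if pca is not None else config.pca_true
    n = len(cohort.eyes)

    est = mean_sia(cohort, zone)
    per_eye = np.array([
        (v.x, v.y) for v in (
            sia_vector(eye_anterior_ca(e, "preop", zone), eye_anterior_ca(e, "postop", zone))
            for e in cohort
        )
    ])
    se = per_eye.std(axis=0, ddof=1) / np.sqrt(n)

    records = build_prediction_records(cohort, zone, "postop_k", pca, config.vertex_distance)
    labels_est = [
        classify_astigmatism(eye_anterior_ca(e, "preop", zone).axis) for e in cohort
    ]
    labels_true = truth.labels()

    centroids: dict[AstigmatismType, tuple[float, float]] = {}
    expected: dict[AstigmatismType, tuple[float, float]] = {}
    for label in _SUBTYPES:
        idx = [i for i, lab in enumerate(labels_true) if lab == label]
        if not idx:
            continue
        ex = float(np.mean([records[i].error.x for i in idx]))
        ey = float(np.mean([records[i].error.y for i in idx]))
        centroids[label] = (ex, ey)
        bias = config.subtype_error[label]
        expected[label] = (bias.x, bias.y)

    return RecoveryReport(
        n=n,
        sia_bias_x=est.x - config.sia_mean.x,
        sia_bias_y=est.y - config.sia_mean.y,
        sia_se_x=float(se[0]),
        sia_se_y=float(se[1]),
        subgroup_centroids=centroids,
        subgroup_expected=expected,
        subgroup_counts_estimated={
            t: sum(1 for lab in labels_est if lab == t) for t in _SUBTYPES
        },
        subgroup_counts_truth={
            t: sum(1 for lab in labels_true if lab == t) for t in _SUBTYPES
        },
    )
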