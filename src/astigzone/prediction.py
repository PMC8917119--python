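"""Residual-astigmatism prediction and per-eye prediction errors.

With a nontoric monofocal IOL in the bag, lenticular astigmatism is removed
and the cornea is essentially the eye's only astigmatic element, so the
postoperative manifest refractive astigmatism — expressed at the corneal
plane — stands in for the total corneal astigmatism.  A prediction of total
corneal astigmatism is therefore directly a prediction of the residual
refractive astigmatism.

Two prediction paths are supported:

``preop_sia``
    anterior keratometric astigmatism measured before surgery, plus a
    posterior-cornea model, plus the cohort-mean surgically induced
    astigmatism (SIA) of the incision.
``postop_k``
    anterior keratometric astigmatism measured after surgery (the incision's
    effect is already in the cornea), plus the posterior-cornea model; no SIA
    term.

The posterior-cornea adjustment is pluggable (:class:`PcaModel`).  The
proprietary toric calculator used clinically publishes no algorithm, so this
package makes the substitution explicit: every report states which model
produced the predictions, and no claim of equivalence with any commercial
calculator is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .types import Cohort, EyeRecord, PolarAstigmatism, SpheroCylinder, OS
from .vectors import (
    DoubleAngleVector,
    from_double_angle,
    keratometric_astigmatism,
    mirror_left_eye,
    to_double_angle,
)

DEFAULT_VERTEX_DISTANCE = 0.012  # metres; configurable everywhere it is used

PATH_PREOP_SIA = "preop_sia"
PATH_POSTOP_K = "postop_k"


# ---------------------------------------------------------------------------
# vertex-distance conversion

def _vertex_power(power: float, distance: float) -> float:
    denom = 1.0 - distance * power
    if denom <= 0:
        raise ValueError(
            f"vergence singularity: power {power} D at vertex distance {distance} m"
        )
    return power / denom


def refraction_to_corneal_plane(
    r: SpheroCylinder, vertex_distance: float = DEFAULT_VERTEX_DISTANCE
) -> SpheroCylinder:
    """Propagate a spectacle-plane refraction to the corneal plane.

    Each principal power P maps to P / (1 - d*P) with d the vertex distance
    in metres; the axes are unchanged.  The result is re-expressed in
    minus-cylinder form.
    """
    p1, p2 = r.principal_powers
    q1 = _vertex_power(p1, vertex_distance)
    q2 = _vertex_power(p2, vertex_distance)
    return SpheroCylinder(q1, q2 - q1, r.axis)


def refraction_to_spectacle_plane(
    r: SpheroCylinder, vertex_distance: float = DEFAULT_VERTEX_DISTANCE
) -> SpheroCylinder:
    """Inverse of :func:`refraction_to_corneal_plane` (P -> P / (1 + d*P))."""
    p1, p2 = r.principal_powers
    q1 = _vertex_power(p1, -vertex_distance)
    q2 = _vertex_power(p2, -vertex_distance)
    return SpheroCylinder(q1, q2 - q1, r.axis)


def refractive_astigmatism(r: SpheroCylinder) -> PolarAstigmatism:
    """Steep-meridian astigmatism of a refraction.

    In minus-cylinder form the recorded axis marks the flat meridian, so the
    steep meridian — the axis convention used for all astigmatism vectors in
    this package — lies at (axis + 90) mod 180, with magnitude |cylinder|.
    """
    if r.cylinder == 0:
        return PolarAstigmatism(0.0, 0.0)
    return PolarAstigmatism(abs(r.cylinder), (r.axis + 90.0) % 180.0)


# ---------------------------------------------------------------------------
# posterior-cornea models

@dataclass(frozen=True)
class PcaModel:
    """A deterministic posterior-cornea adjustment.

    ``predict`` maps the measured anterior corneal astigmatism to the
    posterior contribution (as a polar astigmatism at the total-power level),
    which is added to the anterior component in doubled-angle space.
    """

    name: str
    parameters: dict
    _predict: Callable[[PolarAstigmatism, dict], PolarAstigmatism]

    def predict(self, anterior: PolarAstigmatism) -> PolarAstigmatism:
        return self._predict(anterior, self.parameters)


def _zero_predict(anterior: PolarAstigmatism, params: dict) -> PolarAstigmatism:
    return PolarAstigmatism(0.0, 0.0)


def _fixed_atr_predict(anterior: PolarAstigmatism, params: dict) -> PolarAstigmatism:
    return PolarAstigmatism(params["magnitude"], params["axis"])


def _proportional_predict(anterior: PolarAstigmatism, params: dict) -> PolarAstigmatism:
    axis = params["axis"] if params["axis"] is not None else anterior.axis
    return PolarAstigmatism(params["scale"] * anterior.magnitude, axis)


def zero_pca() -> PcaModel:
    """No posterior-cornea adjustment."""
    return PcaModel("zero", {}, _zero_predict)


def fixed_atr_pca(magnitude: float = 0.30, axis: float = 0.0) -> PcaModel:
    """Constant posterior contribution, by default 0.30 D steep at 180/0.

    The posterior cornea is steeper vertically, which at the total-power
    level acts as a net against-the-rule (horizontal-steep) contribution;
    the default magnitude is a package choice in the range reported across
    the tomography literature, not a fitted value.
    """
    return PcaModel("fixed_atr", {"magnitude": magnitude, "axis": axis}, _fixed_atr_predict)


def proportional_pca(scale: float = 0.3, axis: Optional[float] = None) -> PcaModel:
    """Posterior magnitude proportional to the anterior magnitude.

    ``axis=None`` aligns the posterior contribution with the anterior steep
    meridian; a number fixes the orientation in degrees.
    """
    return PcaModel("proportional", {"scale": scale, "axis": axis}, _proportional_predict)


_BUILTIN_FACTORIES: dict[str, Callable[..., PcaModel]] = {
    "zero": zero_pca,
    "fixed_atr": fixed_atr_pca,
    "proportional": proportional_pca,
}


def builtin_pca_models() -> dict[str, Callable[..., PcaModel]]:
    """Catalogue of built-in posterior-cornea model factories by name."""
    return dict(_BUILTIN_FACTORIES)


def get_pca_model(name: str, **params) -> PcaModel:
    """Instantiate a built-in model by name with keyword parameters."""
    try:
        factory = _BUILTIN_FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown posterior-cornea model {name!r}; "
            f"available: {sorted(_BUILTIN_FACTORIES)}"
        ) from None
    return factory(**params)


# ---------------------------------------------------------------------------
# SIA and prediction

def sia_vector(
    preop_ca: PolarAstigmatism, postop_ca: PolarAstigmatism
) -> DoubleAngleVector:
    """Surgically induced astigmatism: postop minus preop, in doubled space."""
    return to_double_angle(postop_ca) - to_double_angle(preop_ca)


def eye_anterior_ca(eye: EyeRecord, epoch: str, zone: float, mirror: bool = True) -> PolarAstigmatism:
    """Keratometric anterior corneal astigmatism of one eye, mirrored if OS."""
    ca = keratometric_astigmatism(eye.keratometry(epoch, zone))
    if mirror and eye.laterality == OS:
        ca = mirror_left_eye(ca)
    return ca


def mean_sia(cohort: Cohort, zone: float, mirror: bool = True) -> DoubleAngleVector:
    """Cohort-mean SIA vector at a zone (left eyes mirrored first).

    The incision's systematic effect is estimated as the centroid of the
    per-eye preop-to-postop change in keratometric astigmatism; random
    measurement noise averages out of the centroid.
    """
    if not cohort.eyes:
        raise ValueError("cannot compute mean SIA of an empty cohort")
    sx = sy = 0.0
    for eye in cohort:
        v = sia_vector(
            eye_anterior_ca(eye, "preop", zone, mirror),
            eye_anterior_ca(eye, "postop", zone, mirror),
        )
        sx += v.x
        sy += v.y
    n = len(cohort.eyes)
    return DoubleAngleVector(sx / n, sy / n)


def predict_residual(
    eye: EyeRecord,
    zone: float,
    path: str,
    pca: PcaModel,
    sia: Optional[DoubleAngleVector] = None,
    mirror: bool = True,
) -> PolarAstigmatism:
    """Predicted residual refractive astigmatism at the corneal plane.

    Sum, in doubled-angle space, of the anterior keratometric astigmatism at
    the requested epoch, the posterior-cornea model output, and — on the
    ``preop_sia`` path only — the supplied SIA vector.
    """
    if path == PATH_PREOP_SIA:
        if sia is None:
            raise ValueError("preop_sia path requires a SIA vector")
        epoch = "preop"
    elif path == PATH_POSTOP_K:
        if sia is not None:
            raise ValueError("postop_k path must not be given a SIA vector")
        epoch = "postop"
        sia = DoubleAngleVector(0.0, 0.0)
    else:
        raise ValueError(f"unknown prediction path {path!r}")

    anterior = eye_anterior_ca(eye, epoch, zone, mirror)
    total = to_double_angle(anterior) + to_double_angle(pca.predict(anterior)) + sia
    return from_double_angle(total)


def prediction_error(
    predicted: PolarAstigmatism, actual: PolarAstigmatism
) -> DoubleAngleVector:
    """Prediction error as actual − predicted in doubled-angle space.

    Sign convention: positive components mean the achieved astigmatism
    exceeds the prediction along that doubled-angle direction
    (under-prediction).  All paired comparisons are invariant to a global
    sign flip.
    """
    return to_double_angle(actual) - to_double_angle(predicted)


@dataclass(frozen=True)
class PredictionRecord:
    """One eye's prediction, observed outcome and error at one zone/path."""

    eye_id: str
    zone: float
    path: str
    predicted: PolarAstigmatism
    actual: PolarAstigmatism
    error: DoubleAngleVector = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "error", prediction_error(self.predicted, self.actual))


def observed_refractive_astigmatism(
    eye: EyeRecord, vertex_distance: float = DEFAULT_VERTEX_DISTANCE, mirror: bool = True
) -> PolarAstigmatism:
    """Postoperative refractive astigmatism at the corneal plane, mirrored if OS."""
    corneal = refraction_to_corneal_plane(eye.postop_refraction, vertex_distance)
    actual = refractive_astigmatism(corneal)
    if mirror and eye.laterality == OS:
        actual = mirror_left_eye(actual)
    return actual


def build_prediction_records(
    cohort: Cohort,
    zone: float,
    path: str,
    pca: PcaModel,
    vertex_distance: float = DEFAULT_VERTEX_DISTANCE,
) -> list[PredictionRecord]:
    """Run one zone/path prediction over a cohort.

    Left eyes are mirrored before any vector arithmetic; on the
    ``preop_sia`` path the cohort-mean SIA at the zone is computed from the
    same cohort and applied as a single centroid to every eye.
    """
    sia = mean_sia(cohort, zone) if path == PATH_PREOP_SIA else None
    records = []
    for eye in cohort:
        predicted = predict_residual(eye, zone, path, pca, sia)
        actual = observed_refractive_astigmatism(eye, vertex_distance)
        records.append(PredictionRecord(eye.eye_id, zone, path, predicted, actual))
    return records
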