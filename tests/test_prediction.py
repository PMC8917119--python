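"""Vertex conversion, SIA, posterior-cornea models and prediction errors."""

import math

import pytest

from astigzone.prediction import (
    PATH_POSTOP_K,
    PATH_PREOP_SIA,
    build_prediction_records,
    builtin_pca_models,
    fixed_atr_pca,
    get_pca_model,
    mean_sia,
    predict_residual,
    prediction_error,
    proportional_pca,
    refraction_to_corneal_plane,
    refraction_to_spectacle_plane,
    refractive_astigmatism,
    sia_vector,
    zero_pca,
)
from astigzone.synthetic import GeneratorConfig, generate_cohort
from astigzone.types import PolarAstigmatism, SpheroCylinder
from astigzone.vectors import DoubleAngleVector, to_double_angle


class TestVertexConversion:
    def test_zero_power_is_fixed_point(self):
        r = SpheroCylinder(0.0, 0.0, 0.0)
        out = refraction_to_corneal_plane(r, 0.012)
        assert (out.sphere, out.cylinder) == (0.0, 0.0)

    def test_zero_distance_is_identity(self):
        r = SpheroCylinder(-3.25, -1.5, 40.0)
        out = refraction_to_corneal_plane(r, 0.0)
        assert out == r

    def test_hand_computed_meridional_powers(self):
        # principal powers -4.00 / -5.00 map through P/(1 - dP) at d = 12 mm
        r = SpheroCylinder(-4.0, -1.0, 180.0)
        out = refraction_to_corneal_plane(r, 0.012)
        assert out.sphere == pytest.approx(-4.0 / 1.048, abs=5e-4)   # -3.817
        assert out.sphere + out.cylinder == pytest.approx(-5.0 / 1.06, abs=5e-4)  # -4.717
        assert out.cylinder == pytest.approx(-0.90, abs=5e-3)
        assert out.axis == 0.0  # axis unchanged (180 canonicalises to 0)

    def test_round_trip_with_spectacle_plane(self):
        r = SpheroCylinder(-2.75, -1.25, 73.0)
        back = refraction_to_spectacle_plane(refraction_to_corneal_plane(r, 0.012), 0.012)
        assert back.sphere == pytest.approx(r.sphere, abs=1e-12)
        assert back.cylinder == pytest.approx(r.cylinder, abs=1e-12)

    def test_vergence_singularity_raises(self):
        with pytest.raises(ValueError, match="singular"):
            refraction_to_corneal_plane(SpheroCylinder(90.0, 0.0, 0.0), 0.012)


class TestRefractiveAstigmatism:
    def test_minus_cylinder_axis_marks_flat_meridian(self):
        a = refractive_astigmatism(SpheroCylinder(0.0, -1.0, 180.0))
        assert a == PolarAstigmatism(1.0, 90.0)

    def test_zero_cylinder(self):
        assert refractive_astigmatism(SpheroCylinder(-1.0, 0.0, 0.0)).magnitude == 0.0

    def test_plus_cylinder_input_transposes_first(self):
        a = refractive_astigmatism(SpheroCylinder(0.0, 1.0, 90.0))
        assert a == PolarAstigmatism(1.0, 90.0)


class TestSia:
    def test_identical_pre_post_is_zero(self):
        ca = PolarAstigmatism(0.8, 95.0)
        v = sia_vector(ca, ca)
        assert (v.x, v.y) == (0.0, 0.0)

    def test_axis_flip_doubles_in_vector_space(self):
        v = sia_vector(PolarAstigmatism(1.0, 90.0), PolarAstigmatism(1.0, 0.0))
        assert v.x == pytest.approx(2.0, abs=1e-12)
        assert v.y == pytest.approx(0.0, abs=1e-12)

    def test_same_axis_magnitude_change(self):
        v = sia_vector(PolarAstigmatism(0.5, 90.0), PolarAstigmatism(0.7, 90.0))
        assert v.x == pytest.approx(-0.2, abs=1e-12)
        assert v.y == pytest.approx(0.0, abs=1e-12)

    def test_mean_sia_recovers_systematic_effect(self):
        config = GeneratorConfig(n_eyes=500, seed=21)
        cohort, _ = generate_cohort(config)
        est = mean_sia(cohort, 2.4)
        # per-component SE: SIA scatter plus two zone-noise draws
        sd = math.sqrt(config.sia_component_sd**2 + 2 * config.k_noise_sd**2)
        se = sd / math.sqrt(500)
        assert abs(est.x - config.sia_mean.x) < 3 * se
        assert abs(est.y - config.sia_mean.y) < 3 * se

    def test_single_eye_mean_is_that_eye(self, small_cohort):
        cohort, _ = small_cohort
        from astigzone.types import Cohort
        one = Cohort(eyes=[cohort.eyes[0]])
        est = mean_sia(one, 3.3)
        from astigzone.prediction import eye_anterior_ca
        v = sia_vector(eye_anterior_ca(one.eyes[0], "preop", 3.3),
                       eye_anterior_ca(one.eyes[0], "postop", 3.3))
        assert (est.x, est.y) == (v.x, v.y)


class TestPcaModels:
    def test_catalogue_contents(self):
        catalogue = builtin_pca_models()
        assert {"zero", "fixed_atr", "proportional"} <= set(catalogue)
        with pytest.raises(KeyError, match="unknown"):
            get_pca_model("no_such_model")

    def test_zero_model(self):
        assert zero_pca().predict(PolarAstigmatism(2.0, 37.0)).magnitude == 0.0

    def test_fixed_atr_is_constant(self):
        m = fixed_atr_pca(0.30)
        for anterior in (PolarAstigmatism(0.1, 10.0), PolarAstigmatism(2.0, 170.0)):
            out = m.predict(anterior)
            assert out.magnitude == 0.30 and out.axis == 0.0

    def test_proportional_scaling(self):
        m = proportional_pca(0.3)
        out = m.predict(PolarAstigmatism(1.0, 70.0))
        assert out.magnitude == pytest.approx(0.30)
        assert out.axis == 70.0
        fixed_axis = proportional_pca(0.5, axis=0.0).predict(PolarAstigmatism(1.0, 70.0))
        assert fixed_axis.axis == 0.0


class TestPredictResidual:
    def test_postop_path_with_zero_pca_is_pass_through(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        eye = cohort.eyes[0]
        from astigzone.prediction import eye_anterior_ca
        predicted = predict_residual(eye, 2.4, PATH_POSTOP_K, zero_pca())
        measured = eye_anterior_ca(eye, "postop", 2.4)
        assert predicted.magnitude == pytest.approx(measured.magnitude, abs=1e-12)

    def test_fixed_atr_cancels_matching_wtr(self, noiseless_cohort):
        # posterior (0.30 @ 0) exactly cancels an anterior 0.30 @ 90
        cohort, _, _ = noiseless_cohort
        total = to_double_angle(PolarAstigmatism(0.30, 90.0)) + to_double_angle(
            fixed_atr_pca(0.30).predict(PolarAstigmatism(0.30, 90.0)))
        assert math.hypot(total.x, total.y) < 1e-12

    def test_preop_path_requires_sia_and_postop_forbids_it(self, small_cohort):
        cohort, _ = small_cohort
        eye = cohort.eyes[0]
        with pytest.raises(ValueError, match="requires a SIA"):
            predict_residual(eye, 2.4, PATH_PREOP_SIA, zero_pca(), sia=None)
        with pytest.raises(ValueError, match="must not"):
            predict_residual(eye, 2.4, PATH_POSTOP_K, zero_pca(),
                             sia=DoubleAngleVector(0.0, 0.0))

    def test_preop_path_with_zero_sia_equals_postop_path_on_preop_k(self, small_cohort):
        cohort, _ = small_cohort
        import dataclasses
        eye = cohort.eyes[0]
        # give the eye postop K equal to its preop K, then the two paths coincide
        twin = dataclasses.replace(eye, postop_k=dict(eye.preop_k))
        a = predict_residual(twin, 2.4, PATH_PREOP_SIA, fixed_atr_pca(),
                             sia=DoubleAngleVector(0.0, 0.0))
        b = predict_residual(twin, 2.4, PATH_POSTOP_K, fixed_atr_pca())
        assert a.magnitude == pytest.approx(b.magnitude, abs=1e-12)
        assert a.axis == pytest.approx(b.axis, abs=1e-9)


class TestPredictionError:
    def test_perfect_prediction(self):
        p = PolarAstigmatism(0.8, 95.0)
        e = prediction_error(p, p)
        assert (e.x, e.y) == (0.0, 0.0)

    def test_zero_prediction(self):
        e = prediction_error(PolarAstigmatism(0.0, 0.0), PolarAstigmatism(0.5, 0.0))
        assert e.x == pytest.approx(0.5) and e.y == pytest.approx(0.0)

    def test_antisymmetry(self):
        a, b = PolarAstigmatism(0.7, 12.0), PolarAstigmatism(1.1, 144.0)
        e1, e2 = prediction_error(a, b), prediction_error(b, a)
        assert e1.x == pytest.approx(-e2.x) and e1.y == pytest.approx(-e2.y)

    def test_translation_consistency(self):
        from astigzone.vectors import from_double_angle
        a, b = PolarAstigmatism(0.7, 12.0), PolarAstigmatism(1.1, 144.0)
        shift = DoubleAngleVector(0.4, -0.3)
        base = prediction_error(a, b)
        shifted = prediction_error(
            from_double_angle(to_double_angle(a) + shift),
            from_double_angle(to_double_angle(b) + shift),
        )
        assert shifted.x == pytest.approx(base.x, abs=1e-12)
        assert shifted.y == pytest.approx(base.y, abs=1e-12)


def test_build_prediction_records_shapes(small_cohort):
    cohort, _ = small_cohort
    for path in (PATH_PREOP_SIA, PATH_POSTOP_K):
        records = build_prediction_records(cohort, 3.3, path, fixed_atr_pca())
        assert len(records) == len(cohort.eyes)
        for r in records:
            delta = to_double_angle(r.actual) - to_double_angle(r.predicted)
            assert r.error.x == pytest.approx(delta.x, abs=1e-12)
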