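"""Centroid summaries, confidence ellipses, paired tests, regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from astigzone.stats import (
    centroid_summary,
    confidence_ellipse,
    covariate_regression,
    cumulative_magnitude_table,
    paired_zone_comparison,
    subgroup_analysis,
)
from astigzone.vectors import AstigmatismType, DoubleAngleVector


def _vecs(arr):
    return [DoubleAngleVector(float(x), float(y)) for x, y in arr]


class TestCentroidSummary:
    def test_hand_arithmetic_opposite_pair(self):
        s = centroid_summary(_vecs([(1.0, 0.0), (-1.0, 0.0)]))
        assert s.centroid_magnitude == 0.0
        assert s.mean_abs == 1.0
        assert s.sd_x == pytest.approx(math.sqrt(2.0))
        assert s.sd_y == 0.0

    def test_identical_vectors(self):
        s = centroid_summary(_vecs([(0.3, 0.4)] * 5))
        assert s.centroid_magnitude == pytest.approx(0.5)
        assert s.sd_x == s.sd_y == 0.0
        assert s.mean_abs == pytest.approx(0.5)
        assert s.sd_abs == 0.0

    def test_consistent_with_printed_centroid_form(self):
        # a centroid with x = 0.058 and y = 0.069 reads 0.09 D @ 25
        s = centroid_summary(_vecs([(0.058, 0.069)] * 3))
        assert s.centroid_magnitude == pytest.approx(0.09, abs=0.001)
        assert s.centroid_axis == pytest.approx(25.0, abs=0.2)

    def test_combined_sd_is_root_sum_square(self, rng):
        # the definition must be compatible with a component SD of 0.489
        # combining to 0.68: the implied other component lies in (0.45, 0.49)
        sd_y = math.sqrt(0.68**2 - 0.489**2)
        assert 0.45 < sd_y < 0.49
        a = rng.normal(size=(50, 2))
        s = centroid_summary(_vecs(a))
        assert s.combined_sd == pytest.approx(math.hypot(s.sd_x, s.sd_y), abs=1e-12)

    def test_triangle_inequality_and_loop_oracle(self, rng):
        a = rng.normal(scale=0.5, size=(200, 2))
        s = centroid_summary(_vecs(a))
        assert s.mean_abs >= s.centroid_magnitude - 1e-12
        # naive loop oracle
        n = len(a)
        mx = sum(v[0] for v in a) / n
        my = sum(v[1] for v in a) / n
        sdx = math.sqrt(sum((v[0] - mx) ** 2 for v in a) / (n - 1))
        mabs = sum(math.hypot(*v) for v in a) / n
        assert s.mean_x == pytest.approx(mx, abs=1e-12)
        assert s.sd_x == pytest.approx(sdx, abs=1e-12)
        assert s.mean_abs == pytest.approx(mabs, abs=1e-12)

    def test_requires_two_vectors(self):
        with pytest.raises(ValueError):
            centroid_summary(_vecs([(1.0, 0.0)]))


class TestConfidenceEllipse:
    def test_isotropic_dataset_radius_is_chi2_quantile(self, rng):
        # large isotropic unit-variance sample: the 95% dataset ellipse is a
        # circle of radius sqrt(5.991)
        a = rng.standard_normal(size=(20000, 2))
        e = confidence_ellipse(_vecs(a), 0.95, "dataset")
        r = math.sqrt(sps.chi2.ppf(0.95, 2))
        assert e.semi_major == pytest.approx(r, rel=0.05)
        assert e.semi_minor == pytest.approx(r, rel=0.05)

    def test_centroid_ellipse_shrinks_by_sqrt_n(self, rng):
        a = rng.standard_normal(size=(100, 2))
        ds = confidence_ellipse(_vecs(a), 0.95, "dataset")
        ce = confidence_ellipse(_vecs(a), 0.95, "centroid")
        assert ce.semi_major == pytest.approx(ds.semi_major / 10.0, rel=1e-9)
        assert ce.semi_minor == pytest.approx(ds.semi_minor / 10.0, rel=1e-9)

    def test_degenerate_data_flags(self):
        e = confidence_ellipse(_vecs([(0.2, 0.1)] * 5), 0.95, "dataset")
        assert e.degenerate
        assert e.semi_major == 0.0 and e.semi_minor == 0.0
        line = confidence_ellipse(_vecs([(x, 0.0) for x in (-1, 0, 1, 2)]), 0.95, "dataset")
        assert line.degenerate and line.semi_minor == 0.0 and line.semi_major > 0

    def test_orientation_follows_major_axis(self, rng):
        x = rng.standard_normal(5000) * 3.0
        y = rng.standard_normal(5000) * 0.5
        e = confidence_ellipse(_vecs(np.column_stack([x, y])), 0.95, "dataset")
        assert min(e.orientation, 180.0 - e.orientation) < 5.0

    def test_contains_membership(self):
        pts = _vecs([(1, 0), (-1, 0), (0, 1), (0, -1), (0.1, 0.2), (-0.3, 0.4)])
        e = confidence_ellipse(pts, 0.95, "dataset")
        assert e.contains((0.0, 0.0))
        assert not e.contains((100.0, 100.0))

    def test_hotelling_scaling_slightly_wider(self, rng):
        a = rng.standard_normal(size=(30, 2))
        chi = confidence_ellipse(_vecs(a), 0.95, "centroid", scaling="chi2")
        hot = confidence_ellipse(_vecs(a), 0.95, "centroid", scaling="hotelling")
        assert hot.semi_major > chi.semi_major


class TestCumulativeTable:
    def test_examples(self):
        assert cumulative_magnitude_table([0.3, 0.6, 1.2], [0.5, 1.0, 1.5]) == [1, 2, 3]
        assert cumulative_magnitude_table([], [0.5, 1.0]) == [0, 0]
        assert cumulative_magnitude_table([0.1, 0.2], [0.5, 1.0]) == [2, 2]

    def test_monotone_and_ends_at_n(self, rng):
        values = rng.uniform(0, 2, 500)
        thresholds = [0.25, 0.5, 1.0, 2.0]
        counts = cumulative_magnitude_table(values, thresholds)
        assert counts == sorted(counts)
        assert counts[-1] == 500
        # naive loop oracle
        oracle = [sum(1 for v in values if v <= t) for t in thresholds]
        assert counts == oracle

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            cumulative_magnitude_table([0.1], [1.0, 0.5])


class TestPairedComparison:
    def test_identical_lists_give_p_one(self, rng):
        a = _vecs(rng.normal(size=(20, 2)))
        c = paired_zone_comparison(a, a)
        assert c.mean_diff_x == 0.0 and c.mean_diff_y == 0.0
        assert c.p_x == 1.0 and c.p_y == 1.0 and c.p_abs == 1.0

    def test_constant_offset_recovered(self, rng):
        a = rng.normal(size=(30, 2))
        b = a.copy()
        b[:, 0] -= 0.25  # zone-2 x shifted down, with within-pair variance
        b += rng.normal(scale=0.05, size=b.shape)
        c = paired_zone_comparison(_vecs(a), _vecs(b))
        assert c.mean_diff_x == pytest.approx(0.25, abs=0.05)
        assert c.p_x < 0.001
        assert c.p_y > 0.05

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="pairing"):
            paired_zone_comparison(_vecs(rng.normal(size=(5, 2))),
                                   _vecs(rng.normal(size=(6, 2))))


class TestSubgroupAnalysis:
    def test_single_label_matches_global(self, rng):
        a = rng.normal(size=(40, 2))
        labels = [AstigmatismType.WTR] * 40
        out = subgroup_analysis({2.4: _vecs(a), 3.3: _vecs(a * 0.5)}, labels)
        assert set(out) == {AstigmatismType.WTR}
        res = out[AstigmatismType.WTR]
        assert res.n == 40
        global_s = centroid_summary(_vecs(a))
        assert res.summaries[2.4].mean_x == pytest.approx(global_s.mean_x)
        assert res.comparison is not None

    def test_partition_counts(self, rng):
        labels = ([AstigmatismType.WTR] * 47 + [AstigmatismType.ATR] * 33
                  + [AstigmatismType.OBLIQUE] * 21)
        a = rng.normal(size=(101, 2))
        out = subgroup_analysis({2.4: _vecs(a)}, labels)
        assert sum(r.n for r in out.values()) == 101

    def test_small_subgroup_omitted(self, rng):
        labels = [AstigmatismType.WTR] * 10 + [AstigmatismType.ATR]
        a = rng.normal(size=(11, 2))
        out = subgroup_analysis({2.4: _vecs(a)}, labels)
        assert AstigmatismType.ATR not in out


class TestCovariateRegression:
    @staticmethod
    def _frame(rng, n=101):
        return pd.DataFrame({
            "age": rng.uniform(50, 90, n),
            "sex": rng.choice(["M", "F"], n),
            "axial_length": rng.uniform(22, 28, n),
            "iol_power": rng.uniform(6, 28, n),
            "preop_astigmatism": rng.uniform(0.1, 2.0, n),
            "corneal_irregularity": rng.uniform(0.1, 0.6, n),
        })

    def test_noiseless_fit_recovers_coefficient(self, rng):
        df = self._frame(rng)
        df["abs_error"] = 2.0 * df["age"]
        report = covariate_regression(df, ["age"], "abs_error")
        term = report.term("age")
        assert term.coefficient == pytest.approx(2.0, abs=1e-8)
        assert term.p_value < 1e-12

    def test_intercept_only_data(self, rng):
        df = self._frame(rng)
        df["abs_error"] = 0.7
        report = covariate_regression(df, response="abs_error")
        for t in report.terms:
            if t.name != "intercept":
                assert t.coefficient == pytest.approx(0.0, abs=1e-10)
        assert report.term("intercept").coefficient == pytest.approx(0.7)

    def test_univariate_mode_returns_per_covariate(self, rng):
        df = self._frame(rng)
        df["abs_error"] = rng.normal(size=len(df))
        out = covariate_regression(df, response="abs_error", mode="univariate")
        assert set(out) == {"age", "sex", "axial_length", "iol_power",
                            "preop_astigmatism", "corneal_irregularity"}
        assert all(len(r.terms) == 2 for r in out.values())

    def test_null_response_false_positive_rate(self, rng):
        # response independent of every covariate: about 5% of covariate
        # p-values fall below 0.05
        hits = total = 0
        for _ in range(300):
            df = self._frame(rng)
            df["abs_error"] = rng.normal(size=len(df))
            report = covariate_regression(df, response="abs_error")
            for t in report.terms:
                if t.name == "intercept":
                    continue
                total += 1
                hits += t.p_value < 0.05
        rate = hits / total
        assert 0.03 < rate < 0.07
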