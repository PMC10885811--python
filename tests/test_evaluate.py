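"""Agreement statistics against hand computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vinegc import evaluate as ev
from vinegc.exceptions import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedMetricError,
)


class TestErrorMetrics:
    def test_identical_series(self):
        assert ev.error_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        rmse, mae, rel = ev.error_metrics([1.0, 2.0], [2.0, 3.0])
        assert (rmse, mae) == (1.0, 1.0)
        assert rel == pytest.approx(200.0 / 3.0)

    def test_opposite_errors_cancel_in_aggregate_bias(self):
        rmse, mae, rel = ev.error_metrics([1.0, 3.0], [2.0, 2.0])
        assert (rmse, mae) == (1.0, 1.0)
        assert rel == 0.0  # signed errors sum to zero despite mae = 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError, match="mismatch"):
            ev.error_metrics([1.0, 2.0], [1.0])

    def test_zero_observations_make_relative_error_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ev.error_metrics([0.0, 0.0], [1.0, 2.0])

    @given(
        st.lists(st.floats(min_value=-10, max_value=10), min_size=2, max_size=40),
        st.lists(st.floats(min_value=-10, max_value=10), min_size=2, max_size=40),
    )
    def test_rmse_dominates_mae(self, a, b):
        n = min(len(a), len(b))
        obs, est = np.array(a[:n]), np.array(b[:n])
        if abs(obs.sum()) < 1e-9:
            obs = obs + 1.0
        rmse, mae, _ = ev.error_metrics(obs, est)
        assert rmse >= mae - 1e-12

    def test_rmse_equals_mae_iff_errors_equal_magnitude(self):
        rmse, mae, _ = ev.error_metrics([1.0, 2.0, 3.0], [2.0, 1.0, 4.0])
        assert rmse == pytest.approx(mae)


class TestPearson:
    def test_perfect_affine_relations(self):
        obs = np.array([1.0, 2.0, 4.0, 5.0])
        assert ev.pearson_r(obs, obs) == pytest.approx(1.0)
        assert ev.pearson_r(obs, -obs) == pytest.approx(-1.0)
        assert ev.pearson_r(obs, 2 * obs + 1) == pytest.approx(1.0)

    def test_constant_series_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ev.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def normal_equations_ols(x, y):
    """Independent oracle: solve the 2x2 normal equations directly."""
    n = len(x)
    sx, sy, sxx, sxy = np.sum(x), np.sum(y), np.sum(x * x), np.sum(x * y)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


class TestOLS:
    def test_exact_fit_flags_undefined_p(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        fit = ev.ols_with_intercept(obs, 2 * obs + 3)
        assert fit.intercept == pytest.approx(3.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.perfect_fit and np.isnan(fit.intercept_p)

    def test_matches_normal_equations_oracle(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        est = np.array([1.1, 1.9, 3.2, 3.8])
        fit = ev.ols_with_intercept(obs, est)
        b0, b1 = normal_equations_ols(obs, est)
        assert fit.intercept == pytest.approx(b0, abs=1e-10)
        assert fit.slope == pytest.approx(b1, abs=1e-10)
        assert 0 < fit.intercept_p < 1

    def test_true_zero_intercept_rarely_rejected(self, rng):
        obs = np.linspace(1, 2, 100)
        rejections = 0
        for _ in range(200):
            est = obs + rng.normal(0, 0.1, size=obs.size)
            if ev.ols_with_intercept(obs, est).intercept_p < 0.05:
                rejections += 1
        assert rejections / 200 < 0.12  # near the nominal 5% level

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            ev.ols_with_intercept([1.0, 2.0], [1.0, 2.0])


class TestRegressionThroughOrigin:
    def test_exact_proportionality(self):
        obs = np.array([1.0, 2.0, 3.0])
        slope, r = ev.regression_through_origin(obs, 2 * obs)
        assert slope == pytest.approx(2.0) and r == pytest.approx(1.0)

    def test_hand_computed_slope(self):
        slope, _ = ev.regression_through_origin([1.0, 2.0, 3.0], [2.0, 3.0, 5.0])
        assert slope == pytest.approx(23.0 / 14.0, rel=1e-12)

    def test_recovers_field_proportionality_constant(self):
        # a noiseless est = 1.051 * obs series returns exactly that slope
        obs = np.linspace(0.0005, 0.003, 50)
        slope, r = ev.regression_through_origin(obs, 1.051 * obs)
        assert slope == pytest.approx(1.051, rel=1e-12)
        assert r == pytest.approx(1.0)

    def test_uncentered_convention(self):
        obs = np.array([1.0, 2.0, 3.0])
        est = np.array([2.0, 3.0, 5.0])
        slope, r = ev.regression_through_origin(obs, est, r_convention="uncentered")
        expected = np.sqrt(1 - np.sum((est - slope * obs) ** 2) / np.sum(est**2))
        assert r == pytest.approx(expected, rel=1e-12)

    def test_all_zero_obs_rejected(self):
        with pytest.raises(InvalidInputError):
            ev.regression_through_origin([0.0, 0.0], [1.0, 2.0])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_slope_matches_sum_ratio_oracle(self, seed):
        r = np.random.default_rng(seed)
        obs = r.normal(1, 0.5, size=20)
        est = r.normal(1, 0.5, size=20)
        slope, _ = ev.regression_through_origin(obs, est)
        assert slope == pytest.approx(np.sum(obs * est) / np.sum(obs**2), rel=1e-10)


class TestCohensD:
    def test_identical_samples_give_zero(self):
        d, _ = ev.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_unit_separation(self):
        # means 2 and 1, each sample SD 1, equal n -> d = 1
        d, sp = ev.cohens_d([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert d == pytest.approx(1.0) and sp == pytest.approx(1.0)

    def test_antisymmetric_and_scale_invariant(self, rng):
        a, b = rng.normal(2, 1, 30), rng.normal(1, 1.5, 40)
        d_ab, _ = ev.cohens_d(a, b)
        d_ba, _ = ev.cohens_d(b, a)
        d_scaled, _ = ev.cohens_d(5 * a, 5 * b)
        assert d_ab == pytest.approx(-d_ba, rel=1e-12)
        assert d_scaled == pytest.approx(d_ab, rel=1e-10)

    def test_zero_pooled_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ev.cohens_d([1.0, 1.0], [2.0, 2.0])


class TestU1:
    def test_anchor_points(self):
        assert ev.u1_nonoverlap(0.0) == 0.0
        assert ev.u1_nonoverlap(0.2) == pytest.approx(14.7)
        assert ev.u1_nonoverlap(0.3) == pytest.approx(21.3)

    def test_interpolated_value_at_field_effect_size(self):
        assert round(ev.u1_nonoverlap(0.217), 1) == 15.8
        # the exact-normal reading rounds differently, which is why the
        # table convention is the default
        assert round(ev.u1_nonoverlap(0.217, mode="exact_normal"), 1) == 15.9

    def test_monotone_in_effect_size_both_modes(self):
        grid = np.linspace(0, 4, 81)
        for mode in ("table_interpolation", "exact_normal"):
            u = [ev.u1_nonoverlap(d, mode) for d in grid]
            assert np.all(np.diff(u) >= 0)

    def test_modes_agree_within_half_point_for_small_d(self):
        for d in np.linspace(0, 1, 101):
            gap = abs(ev.u1_nonoverlap(d) - ev.u1_nonoverlap(d, "exact_normal"))
            assert gap < 0.5

    def test_sign_of_d_is_ignored(self):
        assert ev.u1_nonoverlap(-0.5) == ev.u1_nonoverlap(0.5)

    def test_beyond_table_falls_back_to_exact(self, caplog):
        with caplog.at_level("WARNING", logger="vinegc.evaluate"):
            u = ev.u1_nonoverlap(5.0)
        assert u == pytest.approx(ev.u1_nonoverlap(5.0, "exact_normal"))
        assert any("beyond" in rec.message for rec in caplog.records)


class TestCV:
    def test_constant_series(self):
        assert ev.coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed(self):
        assert ev.coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ev.coefficient_of_variation([-1.0, 1.0])


class TestEvaluateModel:
    def test_perfect_agreement(self):
        obs = np.linspace(0.001, 0.003, 20)
        rep = ev.evaluate_model(obs, obs.copy())
        assert rep.rmse == 0 and rep.mae == 0 and rep.rel_err_pct == 0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.rto_slope == pytest.approx(1.0)
        assert rep.cohens_d == 0.0 and rep.u1_pct == 0.0
        assert "ols" in rep.flags  # exact fit -> intercept p undefined

    def test_noisy_report_is_finite_and_serializes(self, rng):
        obs = rng.uniform(0.001, 0.003, 100)
        est = obs * 1.05 + rng.normal(0, 1e-4, 100)
        rep = ev.evaluate_model(obs, est)
        d = rep.to_dict()
        for key in ("rmse", "mae", "pearson_r", "rto_slope", "cohens_d", "u1_pct"):
            assert np.isfinite(d[key])
        back = ev.EvaluationReport.from_dict(d)
        assert back.to_dict() == d
        assert "rto_slope" in rep.to_text()

    def test_nan_pairs_excluded_jointly(self):
        obs = np.array([0.001, np.nan, 0.002, 0.003, 0.004])
        est = np.array([0.001, 0.002, np.nan, 0.003, 0.004])
        rep = ev.evaluate_model(obs, est)
        assert rep.n == 3

    def test_cv_matches_component_on_same_data(self, rng):
        obs = rng.uniform(0.001, 0.003, 50)
        est = obs * 1.02
        rep = ev.evaluate_model(obs, est)
        assert rep.cv_obs == pytest.approx(ev.coefficient_of_variation(obs))
        assert rep.cv_est == pytest.approx(ev.coefficient_of_variation(est))

    def test_length_mismatch_raises(self):
        with pytest.raises(InvalidInputError):
            ev.evaluate_model([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_too_few_valid_pairs_raises(self):
        with pytest.raises(InsufficientDataError):
            ev.evaluate_model([1.0, 2.0, np.nan], [1.0, 2.0, 3.0])
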