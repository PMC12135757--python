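"""OLS calibration fits, residual normality, precision statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wearpm.calibration import (
    CalibrationModel,
    apply_calibration,
    fit_ols,
    fit_per_unit,
    fit_universal,
    interunit_cv,
    pairwise_correlations,
    shapiro_wilk,
)
from wearpm.io_logs import resample_to_minutes
from wearpm.steady_state import MatchedInterval, SteadySegment, build_matched_intervals, detect_steady_segments
from wearpm.synthetic import ColocationConfig, PM2_5_UNIT_PARAMS, simulate_colocation

import pandas as pd


def normal_equations(x, y):
    """Independent closed-form OLS oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    sse, sst = np.sum(resid**2), np.sum((y - y.mean()) ** 2)
    return slope, intercept, 1 - sse / sst, np.sqrt(sse / n)


def interval(teom, units, comparison=None):
    seg = SteadySegment(pd.Timestamp("2025-01-01"), pd.Timestamp("2025-01-01 00:05"), 5, teom, 0.0)
    return MatchedInterval(segment=seg, teom_mean=teom, unit_means=dict(units),
                          comparison_mean=comparison)


class TestFitOLS:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = fit_ols(x, 2 * x + 1)
        assert m.slope == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-10)

    def test_three_point_hand_example(self):
        # (1,1),(2,3),(3,4): slope 3/2, intercept -1/3, SSE 1/6, SST 14/3
        m = fit_ols([1, 2, 3], [1, 3, 4])
        assert m.slope == pytest.approx(1.5)
        assert m.intercept == pytest.approx(-1 / 3)
        assert m.r2 == pytest.approx(1 - (1 / 6) / (14 / 3), rel=1e-12)
        assert m.rmse == pytest.approx(np.sqrt((1 / 6) / 3), rel=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 40))
    def test_agrees_with_normal_equations_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 50, n)
        y = rng.uniform(0.5, 4.0) * x + rng.normal(0, 5, n)
        m = fit_ols(x, y)
        slope, intercept, r2, rmse = normal_equations(x, y)
        assert m.slope == pytest.approx(slope, rel=1e-10)
        assert m.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)
        assert m.r2 == pytest.approx(r2, rel=1e-10)
        assert m.rmse == pytest.approx(rmse, rel=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_ols([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_ols([1.0, 2.0], [1.0, 2.0])

    def test_zero_noise_unit_recovery_table_row(self):
        """Inverting a unit with slope 4.48 / intercept -5.17 refits those values."""
        cfg = ColocationConfig(
            unit_params={
                "pm2_5": {u: PM2_5_UNIT_PARAMS["bb1"] for u in ("bb1", "bb2", "bb3")},
                "pm10": {u: (44.3, -81.5) for u in ("bb1", "bb2", "bb3")},
            },
            noise_cv=0.0, teom_noise_cv=0.0, teom_lag_min=0, teom_smoothing_min=0.0, seed=0,
        )
        res = simulate_colocation(cfg)
        segs = detect_steady_segments(resample_to_minutes(res.teom["pm2_5"]))
        matched = build_matched_intervals(segs, 0, res.wearables, None, "pm2_5")
        models = fit_per_unit(matched, "pm2_5")
        assert models["bb1"].slope == pytest.approx(4.48, rel=1e-6)
        assert models["bb1"].intercept == pytest.approx(-5.17, rel=1e-4)


class TestShapiroWilk:
    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(12)
        rejections = sum(
            shapiro_wilk(rng.normal(0, 1, 29))[1] < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_symmetric_three_points_w_near_one(self):
        w, _ = shapiro_wilk([-1.0, 0.0, 1.0])
        assert w > 0.99

    def test_power_against_exponential(self):
        rng = np.random.default_rng(13)
        rejections = sum(
            shapiro_wilk(rng.exponential(1, 50))[1] < 0.05 for _ in range(200)
        )
        assert rejections / 200 >= 0.95

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestUniversal:
    def test_identical_units_equal_per_unit_fit(self):
        rng = np.random.default_rng(5)
        ivs = []
        for _ in range(10):
            t = rng.uniform(5, 150)
            raw = t / 4.0 + rng.normal(0, 0.3)
            ivs.append(interval(t, {"bb1": raw, "bb2": raw, "bb3": raw}))
        uni = fit_universal(ivs, "pm2_5")
        per = fit_per_unit(ivs, "pm2_5")["bb1"]
        assert uni.slope == pytest.approx(per.slope)
        assert uni.intercept == pytest.approx(per.intercept)
        assert uni.unit_id == "averaged"

    def test_zero_noise_closed_form_oracle(self, zero_noise_colocation_config):
        """Universal slope equals the analytic regression on mean((T - a_i)/b_i)."""
        cfg = zero_noise_colocation_config
        cfg.unit_params["pm2_5"] = dict(PM2_5_UNIT_PARAMS)
        res = simulate_colocation(cfg)
        segs = detect_steady_segments(resample_to_minutes(res.teom["pm2_5"]))
        matched = build_matched_intervals(segs, 0, res.wearables, None, "pm2_5")
        uni = fit_universal(matched, "pm2_5")
        # mean raw = T * mean(1/b) - mean(a/b): exact affine, so the fit inverts it
        inv_b = np.mean([1 / b for b, _ in PM2_5_UNIT_PARAMS.values()])
        a_over_b = np.mean([a / b for b, a in PM2_5_UNIT_PARAMS.values()])
        assert uni.slope == pytest.approx(1 / inv_b, rel=1e-6)
        assert uni.intercept == pytest.approx(a_over_b / inv_b, rel=1e-4)
        assert uni.r2 == pytest.approx(1.0)

    def test_mean_universal_slope_recovers_generating_value(self):
        """Parameter recovery over seeded replicates at default noise."""
        inv_b = np.mean([1 / b for b, _ in PM2_5_UNIT_PARAMS.values()])
        truth = 1 / inv_b
        slopes = []
        for seed in range(25):
            res = simulate_colocation(ColocationConfig(seed=seed))
            segs = detect_steady_segments(resample_to_minutes(res.teom["pm2_5"]))
            matched = build_matched_intervals(segs, 4, res.wearables, res.comparison, "pm2_5")
            slopes.append(fit_universal(matched, "pm2_5").slope)
        assert np.mean(slopes) == pytest.approx(truth, rel=0.02)


class TestApplyCalibration:
    def model(self, slope, intercept):
        return CalibrationModel("pm2_5", "averaged", slope, intercept, 1.0, 0.0, 29, 0.0, 1.0, 1.0)

    def test_identity_model_unchanged(self, default_colocation):
        s = default_colocation.wearables[0]
        out = apply_calibration(self.model(1.0, 0.0), s)
        assert out.records["pm2_5"].tolist() == s.records["pm2_5"].tolist()

    def test_affine_on_window_mean(self):
        # corrected window mean = 4.07 * raw mean - 3.82, no per-sample floor
        m = self.model(4.07, -3.82)
        assert float(m.correct(10.0)) == pytest.approx(4.07 * 10 - 3.82)
        assert float(m.correct(0.0)) == pytest.approx(-3.82)  # floored later, at reporting

    def test_refit_after_apply_is_identity(self, default_colocation, default_colocation_minutes):
        segs = detect_steady_segments(default_colocation_minutes["teom"]["pm2_5"])
        matched = build_matched_intervals(
            segs, 4, default_colocation.wearables, default_colocation.comparison, "pm2_5"
        )
        uni = fit_universal(matched, "pm2_5")
        corrected_units = [apply_calibration(uni, u) for u in default_colocation.wearables]
        matched2 = build_matched_intervals(
            segs, 4, corrected_units, default_colocation.comparison, "pm2_5"
        )
        refit = fit_universal(matched2, "pm2_5")
        assert refit.slope == pytest.approx(1.0, abs=1e-9)
        assert refit.intercept == pytest.approx(0.0, abs=1e-6)

    def test_json_roundtrip(self, tmp_path):
        m = self.model(4.07, -3.82)
        p = tmp_path / "m.json"
        m.to_json(p)
        assert CalibrationModel.from_json(p) == m


class TestPrecision:
    def test_identical_units_zero_cv(self):
        ivs = [interval(t, {"bb1": t, "bb2": t, "bb3": t}) for t in (10.0, 20.0, 30.0)]
        assert interunit_cv(ivs) == 0.0

    def test_hand_example_ten_percent(self):
        ivs = [interval(40.0, {"bb1": 9.0, "bb2": 10.0, "bb3": 11.0})] * 2
        assert interunit_cv(ivs) == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        ivs, ivs7 = [], []
        for _ in range(5):
            means = rng.uniform(5, 50, 3)
            ivs.append(interval(1.0, dict(zip("abc", means))))
            ivs7.append(interval(1.0, dict(zip("abc", 7 * means))))
        assert interunit_cv(ivs) == pytest.approx(interunit_cv(ivs7))

    def test_cv_monotone_in_heterogeneity(self):
        base = np.array([10.0, 20.0, 40.0, 80.0])
        cvs = []
        for spread in (0.3, 0.2, 0.1, 0.0):
            deltas = np.array([1 - spread, 1.0, 1 + spread])
            ivs = [interval(t, dict(zip("abc", t * deltas))) for t in base]
            cvs.append(interunit_cv(ivs))
        assert cvs == sorted(cvs, reverse=True)
        assert cvs[-1] == 0.0

    def test_duplicated_unit_r_one(self):
        rng = np.random.default_rng(7)
        ivs = [interval(t, {"a": t / 4 + rng.normal(), "b": 0, "c": 0}) for t in (10.0, 50.0, 90.0, 130.0)]
        for iv in ivs:
            iv.unit_means["b"] = iv.unit_means["a"]
            iv.unit_means["c"] = -iv.unit_means["a"]
        r = pairwise_correlations(ivs)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(r, r.T)
        assert (np.diag(r) == 1).all()

    def test_constant_unit_undefined_entry(self):
        ivs = [interval(t, {"a": t, "b": 5.0}) for t in (10.0, 20.0, 30.0)]
        r = pairwise_correlations(ivs)
        assert np.isnan(r.loc["a", "b"])
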