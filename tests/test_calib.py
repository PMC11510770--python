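import numpy as np
import pandas as pd
import pytest

from portair import (
    DegenerateDesignError,
    InsufficientDataError,
    MetSeries,
    UndefinedMetricError,
    apply_calibration,
    fit_calibration,
    hourly_aggregate,
    r_squared,
    rmse,
    screen_calibration_window,
    validate_colocation,
)
from portair.calib import CalibrationModel
from portair.pipeline import _hourly_met

from conftest import hour_series, met_for


def _colocation(n_hours=72, seed=0, noise_sd=0.0, coefs=(5.0, 2.0, 0.3, -0.1)):
    """Forward-model colocation set: ref = b0 + b1*raw + b2*T + b3*RH (+ noise)."""
    rng = np.random.default_rng(seed)
    idx = pd.date_range(pd.Timestamp("2023-10-21", tz="Asia/Shanghai"),
                        periods=n_hours, freq="h")
    hours = np.arange(n_hours)
    raw = hour_series(rng.uniform(0, 400, n_hours))
    temp = 18 + 6 * np.cos(2 * np.pi * (hours - 14) / 24)
    rh = 65 - 15 * np.cos(2 * np.pi * (hours - 14) / 24) + rng.normal(0, 2, n_hours)
    met = MetSeries(pd.Series(temp, index=idx), pd.Series(rh, index=idx), "hour")
    b0, b1, b2, b3 = coefs
    ref_vals = b0 + b1 * raw.values.to_numpy() + b2 * temp + b3 * rh
    if noise_sd:
        ref_vals = ref_vals + rng.normal(0, noise_sd, n_hours)
    return raw, met, hour_series(ref_vals), coefs


class TestFitCalibration:
    def test_noiseless_recovery_machine_precision(self):
        raw, met, ref, (b0, b1, b2, b3) = _colocation()
        model = fit_calibration(raw, met, ref)
        assert model.intercept == pytest.approx(b0, abs=1e-8)
        assert model.coef_signal == pytest.approx(b1, abs=1e-10)
        assert model.coef_temperature == pytest.approx(b2, abs=1e-9)
        assert model.coef_rh == pytest.approx(b3, abs=1e-9)
        assert model.n_obs == 72

    def test_noisy_recovery_within_three_stderr(self):
        raw, met, ref, (b0, b1, b2, b3) = _colocation(n_hours=200, seed=5, noise_sd=2.0)
        model = fit_calibration(raw, met, ref)
        assert abs(model.coef_signal - b1) < 3 * model.stderr["raw"]
        assert abs(model.coef_temperature - b2) < 3 * model.stderr["temperature"]
        assert abs(model.intercept - b0) < 3 * model.stderr["const"]

    def test_too_few_pairs_rejected(self):
        raw, met, ref, _ = _colocation(n_hours=10)
        with pytest.raises(InsufficientDataError):
            fit_calibration(raw, met, ref)

    def test_constant_rh_is_degenerate(self):
        raw, met, ref, _ = _colocation()
        flat = MetSeries(met.temperature, pd.Series(60.0, index=met.index), "hour")
        with pytest.raises(DegenerateDesignError, match="rh"):
            fit_calibration(raw, flat, ref)

    def test_sensor_network_calibration_improves_accuracy(self, tiny_bundle):
        # error-reduction oracle on a seeded scenario: calibrating against the
        # colocated reference must beat the raw confounded signal
        st = tiny_bundle.channels[("a1", "NO")]
        met = tiny_bundle.met["a1"]
        raw_h = hourly_aggregate(st.raw_sensor, 0.75)
        ref_h = hourly_aggregate(st.total_true, 0.75)
        met_h = _hourly_met(met)
        model = fit_calibration(raw_h, met_h, ref_h)
        calibrated = apply_calibration(model, st.raw_sensor, met)
        assert rmse(calibrated, st.total_true) < rmse(st.raw_sensor, st.total_true)
        # raw sensor was generated with gain 0.85 on the truth
        assert model.coef_signal == pytest.approx(1 / 0.85, rel=0.02)


class TestApplyCalibration:
    def _identity(self):
        t0 = pd.Timestamp("2023-10-21", tz="Asia/Shanghai")
        return CalibrationModel(
            intercept=0.0, coef_signal=1.0, coef_temperature=0.0, coef_rh=0.0,
            fit_window=(t0, t0), n_obs=100, stderr={}, conf_int={},
        )

    def test_identity_model_clips_at_zero(self):
        raw = hour_series([-5.0, 0.0, 12.0, np.nan])
        out = apply_calibration(self._identity(), raw, met_for(raw.index, cadence="hour"))
        np.testing.assert_array_equal(out.values.to_numpy()[:3], [0.0, 0.0, 12.0])
        assert np.isnan(out.values.iloc[3])

    def test_residuals_sum_to_zero_on_fit_window(self):
        raw, met, ref, _ = _colocation(n_hours=120, seed=2, noise_sd=3.0)
        model = fit_calibration(raw, met, ref)
        predicted = model.predict(raw.values, met.temperature, met.relative_humidity)
        assert float((ref.values - predicted).sum()) == pytest.approx(0.0, abs=1e-6)

    def test_grid_mismatch_rejected(self):
        raw = hour_series([1.0, 2.0, 3.0])
        other = met_for(raw.index[:2], cadence="hour")
        with pytest.raises(Exception, match="grid|cover"):
            apply_calibration(self._identity(), raw, other)


class TestMetrics:
    def test_rmse_hand_example(self):
        # sqrt(((2-0)^2 + (2-2)^2) / (2-1)) = 2
        assert rmse([2.0, 2.0], [0.0, 2.0]) == pytest.approx(2.0)

    def test_rmse_identical_series_zero(self):
        x = np.linspace(0, 50, 20)
        assert rmse(x, x) == 0.0

    def test_rmse_uses_n_minus_one(self):
        s, r = np.array([1.0, 2, 3, 4]), np.zeros(4)
        assert rmse(s, r) == pytest.approx(np.sqrt(np.sum(s**2) / 3))

    def test_constant_shift_increases_rmse(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0, 100, 50)
        sensor = ref + rng.normal(0, 5, 50)
        sensor = sensor - np.mean(sensor - ref)  # mean-zero residuals
        base = rmse(sensor, ref)
        assert rmse(sensor + 3.0, ref) > base
        assert rmse(sensor - 3.0, ref) > base

    def test_r_squared_perfect_agreement(self):
        x = np.linspace(1, 9, 15)
        assert r_squared(x, x) == pytest.approx(1.0)

    def test_r_squared_permutation_invariant(self):
        rng = np.random.default_rng(2)
        s, r = rng.uniform(0, 10, 30), rng.uniform(0, 10, 30)
        perm = rng.permutation(30)
        assert r_squared(s, r) == pytest.approx(r_squared(s[perm], r[perm]))

    def test_r_squared_constant_sensor_is_undefined(self):
        # the deployed form's denominator sums sensor deviations around the
        # reference mean, so a sensor pinned at that mean has no spread to
        # normalize by
        with pytest.raises(UndefinedMetricError):
            r_squared([2.0, 2.0], [1.0, 3.0])

    def test_pearson_variant_matches_numpy(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(0, 10, 40)
        s = 2 * r + rng.normal(0, 1, 40)
        assert r_squared(s, r, convention="pearson") == pytest.approx(
            np.corrcoef(s, r)[0, 1] ** 2
        )

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            rmse([1.0], [1.0])

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(5, 60)
            s = rng.uniform(0, 500, n)
            r = rng.uniform(0, 500, n)
            sse = sum((float(a) - float(b)) ** 2 for a, b in zip(s, r))
            rmse_loop = (sse / (n - 1)) ** 0.5
            rbar = sum(map(float, r)) / n
            denom = sum((float(a) - rbar) ** 2 for a in s)
            r2_loop = 1 - sse / denom
            assert rmse(s, r) == pytest.approx(rmse_loop, rel=1e-12)
            assert r_squared(s, r) == pytest.approx(r2_loop, rel=1e-12)

    def test_validate_colocation_bundles_metrics(self, tiny_bundle):
        st = tiny_bundle.channels[("a1", "NO")]
        vm = validate_colocation(
            hourly_aggregate(st.total_true), hourly_aggregate(st.total_true)
        )
        assert vm.r2 == pytest.approx(1.0)
        assert vm.rmse == 0.0
        assert vm.n == 96


class TestScreening:
    def test_warns_on_low_span_and_humid_window(self):
        ref = hour_series([10.0] * 72)  # never exceeds 50 ppb worth of NO
        met = met_for(ref.index, temp=20.0, rh=90.0, cadence="hour")
        with pytest.warns(UserWarning):
            notes = screen_calibration_window(ref, met, ugm3_per_ppb=1.25)
        assert len(notes) == 2

    def test_silent_on_good_window(self, recwarn):
        vals = np.linspace(5, 200, 72)
        ref = hour_series(vals)
        met = met_for(ref.index, temp=20.0, rh=60.0, cadence="hour")
        assert screen_calibration_window(ref, met, ugm3_per_ppb=1.25) == []
        assert len(recwarn) == 0
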