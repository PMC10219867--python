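"""Unit tests for the Holt-Winters model: initialization, recursion fixed
points, closed-form forecasts, fitting degeneracies, and the equivariance
properties of the additive/multiplicative variants."""

import numpy as np
import pandas as pd
import pytest

from edwarn.ets import (EtsParams, EtsSpec, HoltWinters, InsufficientHistoryError,
                        MODEL_IDS)

PARAMS = EtsParams(alpha=0.3, beta=0.1, gamma=0.2, phi=0.9)


class TestInitialization:
    def test_constant_series_has_flat_states(self):
        mod = HoltWinters([5.0] * 12, seasonal_periods=4)
        st = mod.initialize_states()
        assert st.level == 5.0
        assert st.trend == 0.0
        np.testing.assert_allclose(st.season, 0.0)

    def test_periodic_series_decomposes_exactly(self):
        v = np.array([3.0, 7.0, 5.0, 1.0])
        mod = HoltWinters(np.tile(v, 3), seasonal_periods=4)
        st = mod.initialize_states()
        assert st.level == v.mean()
        assert st.trend == 0.0
        np.testing.assert_allclose(st.season, v - v.mean())

    def test_multiplicative_ratio_initialization(self):
        mod = HoltWinters([10, 20, 10, 20, 10, 20], variant="multiplicative",
                          seasonal_periods=2)
        st = mod.initialize_states()
        assert st.level == 15.0
        assert st.trend == 0.0
        np.testing.assert_allclose(st.season, [2 / 3, 4 / 3])

    def test_too_short_series_rejected(self):
        with pytest.raises(InsufficientHistoryError):
            HoltWinters(np.ones(47), seasonal_periods=24)


class TestSmoothing:
    def test_exact_seasonal_init_is_fixed_point(self):
        from edwarn.ets import EtsState
        y = np.array([10.0, 20.0] * 20)
        mod = HoltWinters(y, seasonal_periods=2)
        init = EtsState(15.0, 0.0, np.array([-5.0, 5.0]))
        traj = mod.smooth(EtsParams(0.7, 0.3, 0.4), init=init)
        np.testing.assert_allclose(traj.resid, 0.0, atol=1e-12)
        np.testing.assert_allclose(traj.level, 15.0)
        np.testing.assert_allclose(traj.trend, 0.0, atol=1e-12)

    def test_constant_series_zero_residuals(self):
        mod = HoltWinters([4.0] * 30, seasonal_periods=3)
        traj = mod.smooth(EtsParams(0.5, 0.1, 0.1))
        np.testing.assert_allclose(traj.resid, 0.0, atol=1e-12)

    def test_out_of_bounds_params_rejected(self):
        mod = HoltWinters([4.0] * 30, seasonal_periods=3)
        with pytest.raises(ValueError):
            mod.smooth(EtsParams(1.2, 0.1, 0.1))


class TestForecast:
    def test_additive_closed_form(self):
        # l=70, b=1, seasonal +10 at the k=2 position -> 70 + 2*1 + 10 = 82
        from edwarn.ets import EtsState
        y = np.ones(48) * 70
        mod = HoltWinters(y, seasonal_periods=24)
        res = mod.filter(EtsParams(0.0, 0.0, 0.0))
        res.final_state.level = 70.0
        res.final_state.trend = 1.0
        res.final_state.season = np.zeros(24)
        res.final_state.season[1] = 10.0
        f = np.asarray(res.forecast(24))
        assert f[1] == pytest.approx(82.0)

    def test_constant_model_forecasts_constant(self):
        res = HoltWinters([7.0] * 48, seasonal_periods=24).fit()
        np.testing.assert_allclose(np.asarray(res.forecast(24)), 7.0, atol=1e-8)

    def test_damped_forecast_converges_geometrically(self):
        y = 50 + np.tile(np.arange(24.0), 4)
        mod = HoltWinters(y, variant="damped", seasonal_periods=24)
        res = mod.filter(PARAMS)
        st = res.final_state
        f = np.asarray(res.forecast(24 * 200, floor=False))
        phi = PARAMS.phi
        limit = st.level + st.trend * phi / (1 - phi) + st.season[23]
        assert f[-1] == pytest.approx(limit, rel=1e-6)

    def test_additive_trend_grows_linearly(self):
        y = np.arange(96.0)
        res = HoltWinters(y, seasonal_periods=24).fit()
        f = np.asarray(res.forecast(96, floor=False))
        steps = np.diff(f[::24])
        np.testing.assert_allclose(steps, steps[0], rtol=1e-6)

    @pytest.mark.parametrize("variant", list(MODEL_IDS))
    def test_noiseless_periodic_zero_error(self, variant):
        cycle = 30 + 10 * np.sin(2 * np.pi * np.arange(24) / 24)
        y = np.tile(cycle, 8)
        res = HoltWinters(y, variant=variant, seasonal_periods=24).fit()
        f = np.asarray(res.forecast(24))
        np.testing.assert_allclose(f, cycle, atol=1e-6)

    def test_count_forecasts_floored_at_zero(self):
        y = np.concatenate([np.linspace(40, 2, 96), np.zeros(24)]) \
            + np.tile([0, 1.0], 60)
        res = HoltWinters(y, seasonal_periods=24).fit()
        assert (np.asarray(res.forecast(24)) >= 0).all()

    def test_invalid_horizon(self):
        res = HoltWinters([7.0] * 48, seasonal_periods=24).fit()
        with pytest.raises(ValueError):
            res.forecast(0)


class TestEquivariance:
    rng = np.random.default_rng(5)
    y = 40 + 8 * np.sin(2 * np.pi * np.arange(240) / 24) + rng.normal(0, 1.5, 240)

    def test_additive_shift_equivariance(self):
        f0 = np.asarray(HoltWinters(self.y, seasonal_periods=24).fit().forecast(24))
        f1 = np.asarray(HoltWinters(self.y + 100, seasonal_periods=24).fit().forecast(24))
        np.testing.assert_allclose(f1, f0 + 100, atol=1e-4)

    def test_multiplicative_scale_equivariance(self):
        mk = lambda y: np.asarray(HoltWinters(y, variant="multiplicative",
                                              seasonal_periods=24).fit().forecast(24))
        np.testing.assert_allclose(mk(self.y * 3), 3 * mk(self.y), rtol=1e-4)


class TestFitting:
    def test_multiplicative_offset_on_zero_counts(self):
        rng = np.random.default_rng(9)
        lam = np.tile(np.r_[np.zeros(6) + 0.3, np.linspace(2, 10, 18)], 10)
        y = rng.poisson(lam).astype(float)
        assert (y == 0).any()
        mod = HoltWinters(y, variant="multiplicative", seasonal_periods=24)
        assert mod.offset == 0.5
        f = np.asarray(mod.fit().forecast(24))
        assert np.isfinite(f).all() and (f >= 0).all()

    def test_summary_reports_estimates(self, seasonal_series):
        res = HoltWinters(seasonal_series, variant="damped", seasonal_periods=24).fit()
        text = res.summary()
        assert "HWDM" in text and "phi" in text
        assert 0 <= res.params.alpha <= 1
        assert res.sigma2 > 0

    def test_datetime_index_propagates_to_forecast(self, seasonal_series):
        res = HoltWinters(seasonal_series, seasonal_periods=24).fit()
        f = res.forecast(3)
        assert isinstance(f, pd.Series)
        assert f.index[0] == seasonal_series.index[-1] + pd.Timedelta(hours=1)
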