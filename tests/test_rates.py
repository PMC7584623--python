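import numpy as np
import pandas as pd
import pytest

from floatbloom import rates
from floatbloom.errors import EmptyClimatologyError
from floatbloom.profiles import DerivedProfile


def cast(t_days, mld, pbar, pint=None, float_id="F"):
    return DerivedProfile(
        float_id=float_id,
        cast_time=pd.Timestamp("2016-01-01") + pd.Timedelta(days=t_days),
        latitude=-45.0, longitude=0.0, under_ice=False,
        mld=mld, pbar=pbar, pint_mld=pbar * mld if pint is None else pint,
    )


class TestSwitchingAlgorithm:
    def test_equal_concentration_shoaling_is_zero(self):
        obs = rates.net_rate_of_change(cast(0, 100, 10), cast(10, 50, 10))
        assert obs.branch == "concentration"
        assert obs.r == 0.0

    def test_inventory_hand_value(self):
        obs = rates.net_rate_of_change(cast(0, 50, 2, pint=100), cast(10, 60, 2, pint=110))
        assert obs.branch == "inventory"
        assert obs.r == pytest.approx((2 / 10) * (10 / 210))
        assert obs.midpoint_time == pd.Timestamp("2016-01-06")

    def test_pure_dilution_is_zero(self):
        # deepening halves concentration, conserves inventory -> ecological r = 0
        obs = rates.net_rate_of_change(cast(0, 50, 10, pint=500), cast(10, 100, 5, pint=500))
        assert obs.branch == "inventory" and obs.r == 0.0

    def test_pure_detrainment_is_zero(self):
        # shoaling conserves concentration, loses inventory -> ecological r = 0
        obs = rates.net_rate_of_change(cast(0, 100, 10, pint=1000), cast(10, 50, 10, pint=500))
        assert obs.branch == "concentration" and obs.r == 0.0

    def test_stationary_uses_inventory(self):
        obs = rates.net_rate_of_change(cast(0, 80, 10), cast(10, 80, 11))
        assert obs.branch == "inventory"

    def test_max_gap_skips(self):
        assert rates.net_rate_of_change(cast(0, 80, 10), cast(25, 70, 11)) is None

    def test_exponential_growth_matches_tanh(self):
        k, dt = 0.05, 10.0
        obs = rates.net_rate_of_change(
            cast(0, 100, 10.0), cast(dt, 50, 10.0 * np.exp(k * dt))
        )
        assert obs.r == pytest.approx((2 / dt) * np.tanh(k * dt / 2), abs=1e-12)

    def test_small_rate_relative_error(self):
        # kdt <= 0.2: the centered ratio estimator is within 0.5% of k
        k, dt = 0.02, 10.0
        obs = rates.net_rate_of_change(
            cast(0, 100, 10.0), cast(dt, 50, 10.0 * np.exp(k * dt))
        )
        assert abs(obs.r - k) / k < 0.005

    def test_build_rate_series_pairs_per_float(self):
        derived = pd.DataFrame(
            [vars(cast(t, 100 - t, 10 + 0.1 * t, float_id=f)) for f in "AB" for t in (0, 10, 20)]
        )[["float_id", "cast_time", "mld", "pbar", "pint_mld"]]
        out = rates.build_rate_series(derived)
        assert len(out) == 4  # two pairs per float
        assert set(out.float_id) == {"A", "B"}


class TestSmoothSeries:
    def test_constant_unchanged(self):
        t = np.arange(0.0, 100.0)
        out = rates.smooth_series(t, np.full(100, 3.0), 10, 7)
        np.testing.assert_allclose(out, 3.0)

    def test_outlier_attenuated(self):
        t = np.arange(0.0, 200.0)
        v = np.zeros(200)
        v[100] = 1.0
        out = rates.smooth_series(t, v, 11, 1)
        assert out[100] == pytest.approx(1 / 11, rel=1e-6)

    def test_linear_interior_unchanged(self):
        t = np.arange(0.0, 100.0)
        v = 2.0 * t + 1.0
        out = rates.smooth_series(t, v, 10, 9)
        np.testing.assert_allclose(out[20:80], v[20:80], rtol=1e-12)

    def test_empty(self):
        assert rates.smooth_series(np.array([]), np.array([]), 10, 5).size == 0


class TestWeeklyClimatology:
    def test_constant(self):
        doy = np.tile(np.arange(1, 366), 2)
        cyc = rates.weekly_climatology(doy, np.full(doy.size, 4.2))
        np.testing.assert_allclose(cyc.daily, 4.2)
        assert cyc.daily.size == 365

    def test_sinusoid_amplitude_and_phase(self):
        doy = np.tile(np.arange(1, 366), 3)
        v = np.sin(2 * np.pi * (doy - 1) / 365.0)
        cyc = rates.weekly_climatology(doy, v, smoothing_window_days=60.0)
        # closed-form response: weekly binning then a 9-knot circular average
        f = 2 * np.pi / 365.0
        gain_bin = np.mean(np.cos(f * (np.arange(7) - 3)))
        gain_win = np.mean(np.cos(f * 7.0 * np.arange(-4, 5)))
        days = np.arange(1, 366)
        design = np.column_stack([np.sin(f * (days - 1)), np.cos(f * (days - 1))])
        coef, *_ = np.linalg.lstsq(design, cyc.daily, rcond=None)
        amplitude = np.hypot(*coef)
        phase_shift_days = np.arctan2(coef[1], coef[0]) / f
        assert amplitude == pytest.approx(gain_bin * gain_win, rel=0.02)
        assert abs(phase_shift_days) < 2.0

    def test_circular_continuity(self):
        doy = np.tile(np.arange(1, 366), 2)
        v = np.cos(2 * np.pi * (doy - 20) / 365.0)
        cyc = rates.weekly_climatology(doy, v)
        assert abs(cyc.daily[-1] - cyc.daily[0]) < 0.05

    def test_low_coverage_warns(self):
        doy = np.arange(1, 150)
        with pytest.warns(UserWarning, match="low-coverage"):
            rates.weekly_climatology(doy, np.ones(doy.size))

    def test_empty_raises(self):
        with pytest.raises(EmptyClimatologyError):
            rates.weekly_climatology(np.array([1, 2]), np.array([np.nan, np.nan]))

    def test_feb29_folds_to_365(self):
        doy = rates.day_of_year_365(pd.to_datetime(["2016-02-29", "2016-03-01", "2015-12-31"]))
        np.testing.assert_array_equal(doy, [365, 60, 365])


class TestTemporalDerivative:
    def test_constant_zero(self):
        np.testing.assert_allclose(rates.temporal_derivative(np.full(365, 2.0)), 0.0)

    def test_sinusoid_matches_analytic(self):
        d = np.arange(365)
        x = np.sin(2 * np.pi * d / 365.0)
        dx = rates.temporal_derivative(x)
        expected = (2 * np.pi / 365.0) * np.cos(2 * np.pi * d / 365.0)
        np.testing.assert_allclose(dx, expected, atol=2e-4)

    def test_circular_sum_zero(self, rng):
        x = rng.normal(size=365)
        assert abs(rates.temporal_derivative(x).sum()) < 1e-10
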