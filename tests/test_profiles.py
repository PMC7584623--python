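import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floatbloom import profiles as prof
from floatbloom.errors import InvalidParameterError, UnusableCastError
from floatbloom.seawater import salinity_for_density, sigma0


def make_profile(depth, sal, temp=None, **kw):
    depth = np.asarray(depth, dtype=float)
    temp = np.full(depth.size, 5.0) if temp is None else np.asarray(temp, dtype=float)
    defaults = dict(
        float_id="T1", cast_time=pd.Timestamp("2016-03-01"), latitude=-45.0,
        longitude=10.0, depth=depth, temperature=temp, salinity=np.asarray(sal, dtype=float),
        bbp700=np.full(depth.size, 1e-3), chl=np.full(depth.size, 0.3),
    )
    defaults.update(kw)
    return prof.FloatProfile(**defaults)


def density_profile(depth, sigma_target, temp=5.0):
    """Salinity profile that reproduces a target potential-density profile."""
    t = np.full(len(depth), temp)
    return salinity_for_density(np.asarray(sigma_target, dtype=float), t)


class TestMedianSmoother:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([1, 1, 9, 1, 1, 1, 1], [1, 1, 1, 1, 1, 1, 1]),   # spike rejected
            ([3, 3, 3, 3, 3], [3, 3, 3, 3, 3]),               # constants are fixed points
        ],
    )
    def test_examples(self, series, expected):
        out = prof.smooth_profile_vertical(np.array(series, dtype=float), 7)
        np.testing.assert_allclose(out, expected)

    def test_strictly_increasing_unchanged_at_center(self):
        out = prof.smooth_profile_vertical(np.arange(1.0, 8.0), 7)
        assert out[3] == 4.0

    def test_even_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            prof.smooth_profile_vertical(np.ones(5), 4)

    def test_missing_values_excluded_and_preserved(self):
        x = np.array([1.0, np.nan, 3.0, 100.0, 3.0, np.nan, 1.0])
        out = prof.smooth_profile_vertical(x, 3)
        assert np.isnan(out[1]) and np.isnan(out[5])
        assert out[3] == 3.0  # median of {3, 100, 3}

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40))
    def test_idempotent_on_monotone(self, values):
        x = np.sort(np.array(values))
        once = prof.smooth_profile_vertical(x, 7)
        twice = prof.smooth_profile_vertical(once, 7)
        np.testing.assert_allclose(once, twice)


class TestMld:
    def test_two_layer_jump(self):
        depth = np.arange(5.0, 205.0, 5.0)
        sig = np.where(depth <= 50.0, 26.0, 26.1)
        p = make_profile(depth, density_profile(depth, sig))
        est = prof.estimate_mld(p)
        assert est.reached
        assert abs(est.mld - 50.0) <= 5.0  # within one sample spacing

    def test_uniform_not_reached(self):
        depth = np.arange(5.0, 2001.0, 50.0)
        p = make_profile(depth, density_profile(depth, np.full(depth.size, 26.0)))
        est = prof.estimate_mld(p)
        assert not est.reached
        assert est.mld == depth[-1]

    def test_linear_gradient_hits_40m(self):
        depth = np.arange(5.0, 205.0, 5.0)
        sig = 26.0 + 0.001 * np.clip(depth - 10.0, 0.0, None)
        p = make_profile(depth, density_profile(depth, sig))
        est = prof.estimate_mld(p)
        assert est.mld == pytest.approx(40.0, abs=0.2)

    def test_resampling_invariance(self):
        for spacing in (2.0, 5.0, 10.0):
            depth = np.arange(5.0, 200.0, spacing)
            sig = 26.0 + 0.003 * np.clip(depth - 60.0, 0.0, None)
            p = make_profile(depth, density_profile(depth, sig))
            assert prof.estimate_mld(p).mld == pytest.approx(70.0, abs=spacing)

    def test_all_missing_raises(self):
        depth = np.arange(5.0, 100.0, 5.0)
        p = make_profile(depth, np.full(depth.size, np.nan))
        with pytest.raises(UnusableCastError):
            prof.estimate_mld(p)

    def test_eos_sanity(self):
        # denser when colder and saltier; typical ocean magnitudes
        assert sigma0(35.0, 10.0) > sigma0(34.0, 10.0)
        assert sigma0(35.0, 2.0) > sigma0(35.0, 10.0)
        assert 26.0 < sigma0(35.0, 10.0) < 28.0


class TestEuphoticDepth:
    def test_constant_kd_hundred_meters(self):
        # chl chosen so Kd = 0.046 m-1 -> 1% depth at ln(100)/0.046 = 100.1 m
        chl_const = ((0.046 - 0.0166) / 0.0773) ** (1 / 0.672)
        depth = np.arange(2.0, 201.0, 2.0)
        res = prof.euphotic_depth(np.full(depth.size, chl_const), depth, surface_par=30.0)
        assert not res.dark
        assert res.zeu == pytest.approx(np.log(100.0) / 0.046, rel=0.01)

    def test_doubled_kd_halves_depth(self):
        depth = np.arange(2.0, 301.0, 2.0)
        chl1 = ((0.046 - 0.0166) / 0.0773) ** (1 / 0.672)
        chl2 = ((0.092 - 0.0166) / 0.0773) ** (1 / 0.672)
        z1 = prof.euphotic_depth(np.full(depth.size, chl1), depth, 30.0).zeu
        z2 = prof.euphotic_depth(np.full(depth.size, chl2), depth, 30.0).zeu
        assert z2 == pytest.approx(z1 / 2, rel=0.02)

    def test_darkness(self):
        res = prof.euphotic_depth(np.full(10, 0.3), np.arange(5.0, 55.0, 5.0), 0.0)
        assert res.zeu == 0.0 and res.dark

    def test_capped_at_deepest_sample(self):
        depth = np.arange(5.0, 51.0, 5.0)  # clear water, 1% light below 50 m
        res = prof.euphotic_depth(np.zeros(depth.size), depth, 30.0)
        assert res.zeu == depth[-1]


class TestMixedLayerStats:
    def test_uniform(self):
        depth = np.arange(5.0, 105.0, 5.0)
        cp = np.full(depth.size, 10.0)
        pbar, pint_mld, pint_h = prof.mixed_layer_stats(depth, cp, mld=50.0, horizon=100.0)
        assert pbar == pytest.approx(10.0)
        assert pint_mld == pytest.approx(500.0)
        assert pint_h == pytest.approx(1000.0)

    def test_linear_decline(self):
        depth = np.linspace(0.0, 100.0, 21)
        cp = 10.0 * (1.0 - depth / 100.0)
        pbar, pint_mld, _ = prof.mixed_layer_stats(depth, cp, mld=100.0)
        assert pbar == pytest.approx(5.0)
        assert pint_mld == pytest.approx(500.0)

    @pytest.mark.parametrize("mld", [23.0, 50.0, 87.5, 140.0])
    def test_uniform_invariant_pint_equals_pbar_times_mld(self, mld):
        depth = np.concatenate([np.arange(5.0, 101.0, 5.0), np.arange(110.0, 201.0, 10.0)])
        cp = np.full(depth.size, 7.3)
        pbar, pint_mld, _ = prof.mixed_layer_stats(depth, cp, mld=mld)
        assert abs(pint_mld / mld - pbar) / pbar < 0.01

    def test_too_few_samples_raises(self):
        with pytest.raises(UnusableCastError):
            prof.mixed_layer_stats(np.array([5.0, 60.0]), np.array([1.0, 1.0]), mld=10.0)
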