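import dataclasses

import numpy as np
import pandas as pd
import pytest

from floatbloom import io, pipeline, profiles as prof, synthetic


class TestConfig:
    def test_validation_lists_offenders(self):
        cfg = synthetic.TruthConfig(n_floats=0, cadence_days=7, mld_winter_max=10.0)
        with pytest.raises(ValueError) as err:
            cfg.validate()
        msg = str(err.value)
        assert "n_floats" in msg and "cadence" in msg

    def test_closure_preset_has_constant_mixed_layer(self):
        cfg = synthetic.TruthConfig.closure()
        assert cfg.mld_winter_max - cfg.mld_summer_min < 0.01
        assert cfg.budget_offset < 1e-6


class TestTruthDynamics:
    def test_balanced_budget_constant_biomass(self):
        # no lag, no NSI seasonality, constant mixed layer: mu == l, so P-bar is constant
        cfg = synthetic.TruthConfig.closure(
            n_floats=2, n_years=1, loss_lag_days=0, nsi_amp=0.0, spinup_years=0, seed=0
        )
        truth = synthetic.simulate_truth(cfg)
        for _, grp in truth.groupby("float_id"):
            assert np.ptp(grp.pbar.to_numpy()) / grp.pbar.iloc[0] < 1e-4

    def test_deepening_dilutes_concentration_conserves_inventory(self):
        # mu == l and no budget offset: any P-bar change is entrainment dilution
        cfg = synthetic.TruthConfig(
            n_floats=1, n_years=1, loss_lag_days=0, nsi_amp=0.0,
            loss_budget_offset=0.0, spinup_years=0, seed=0,
        ).noise_free()
        truth = synthetic.simulate_truth(cfg)
        g = truth[truth.float_id == "SYN000"].reset_index(drop=True)
        deep = np.diff(g.mld.to_numpy()) > 0
        dpbar = np.diff(g.pbar.to_numpy())
        dpint = np.diff(g.pint.to_numpy())
        assert np.all(dpbar[deep] < 0)
        np.testing.assert_allclose(dpint[deep], 0.0, atol=1e-9)

    def test_bloom_initiation_near_mu_minimum(self):
        # the lagged-loss balance puts r > 0 once d(mu)/dt stops being strongly
        # negative: initiation happens around the winter mu minimum, months before
        # the mu maximum, echoing the disturbance-recovery phenology
        from floatbloom import phenology
        cfg = synthetic.TruthConfig(n_floats=1, n_years=1, seed=0).noise_free()
        truth = synthetic.simulate_truth(cfg)
        g = truth[truth.float_id == "SYN000"].iloc[:365]
        ev = phenology.detect_bloom_events(g.r.to_numpy())
        assert ev.bi_day is not None
        mu = g.mu.to_numpy()
        mu_min_day = int(np.argmin(mu)) + 1
        mu_max_day = int(np.argmax(mu)) + 1
        assert abs(ev.bi_day - mu_min_day) <= 40
        # the blooming phase runs from near the mu minimum through the mu maximum
        assert ev.blooming_mask[mu_max_day - 1]
        assert not ev.blooming_mask[(mu_min_day - 40) % 365]


class TestEmission:
    def test_mld_recovered_exactly(self, small_dataset):
        truth, profiles = small_dataset
        tr = truth.set_index(["float_id", "date"])
        for p in profiles[::17]:
            est = prof.estimate_mld(p)
            assert est.mld == pytest.approx(tr.loc[(p.float_id, p.cast_time)].mld, abs=1e-6)

    def test_mu_recovered_noise_free(self, small_pipeline):
        truth, derived, _, _ = small_pipeline
        m = derived.merge(truth, left_on=["float_id", "cast_time"], right_on=["float_id", "date"])
        m = m[m.mu_ml.notna()]
        rel = np.abs(m.mu_ml - m.mu) / m.mu
        assert len(m) > 300
        assert rel.max() < 0.01

    def test_bbp_inversion_round_trip(self, small_dataset):
        from floatbloom import biomass
        truth, profiles = small_dataset
        tr = truth.set_index(["float_id", "date"])
        p = profiles[40]
        row = tr.loc[(p.float_id, p.cast_time)]
        cp = biomass.correct_deep_offset(
            biomass.cphyto_from_poc(biomass.poc_from_bbp(p.bbp700)), p.depth
        ).values
        ml = p.depth <= row.mld
        np.testing.assert_allclose(cp[ml], row.pbar, rtol=1e-9)

    def test_determinism_byte_exact(self):
        cfg = synthetic.TruthConfig(n_floats=2, n_years=1, seed=11)
        a = synthetic.emit_float_profiles(synthetic.simulate_truth(cfg), cfg)
        b = synthetic.emit_float_profiles(synthetic.simulate_truth(cfg), cfg)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert pa.bbp700.tobytes() == pb.bbp700.tobytes()
            assert pa.chl.tobytes() == pb.chl.tobytes()

    def test_noise_seeds_differ(self):
        cfg1 = synthetic.TruthConfig(n_floats=1, n_years=1, seed=1)
        cfg2 = dataclasses.replace(cfg1, seed=2)
        truth = synthetic.simulate_truth(cfg1)
        a = synthetic.emit_float_profiles(truth, cfg1)
        b = synthetic.emit_float_profiles(truth, cfg2)
        assert not np.array_equal(a[0].bbp700, b[0].bbp700)

    def test_under_ice_casts_lose_position(self):
        cfg = synthetic.TruthConfig(
            n_floats=2, n_years=1, lat_range=(-62.0, -66.0), seed=3
        ).noise_free()
        profiles = synthetic.emit_float_profiles(synthetic.simulate_truth(cfg), cfg)
        iced = [p for p in profiles if p.under_ice]
        assert iced
        for p in iced:
            assert not p.has_position and np.isnan(p.par0)

    def test_argo_grid_shape(self):
        z = synthetic.argo_depth_grid()
        assert z[0] == 5.0 and z[-1] == 2000.0
        assert np.all(np.diff(z) > 0)
        assert np.all(np.diff(z[z <= 100]) == 5.0)
        assert np.all(np.diff(z[(z >= 110) & (z <= 360)]) == 10.0)
        assert np.all(np.diff(z[z >= 450]) == 50.0)


class TestIronDatabase:
    def test_zone_means_recovered(self):
        db = synthetic.simulate_iron_db(n_points=800, seed=5)
        for zone, mean in synthetic.DEFAULT_IRON_ZONE_MEANS.items():
            sub = db[db.zone == zone]
            se = sub.fe_nmol_kg.std() / np.sqrt(len(sub))
            assert abs(sub.fe_nmol_kg.mean() - mean) < 2 * se + 1e-3

    def test_subtropics_above_point_two(self):
        db = synthetic.simulate_iron_db(n_points=400, seed=5)
        assert db[db.zone == "STZ"].fe_nmol_kg.mean() > 0.2

    def test_empty_database(self):
        db = synthetic.simulate_iron_db(n_points=0)
        assert db.empty
        assert np.isnan(io.match_iron(-45.0, 0.0, pd.Timestamp("2016-01-01"), db))

    def test_deep_only_points_do_not_match(self):
        db = pd.DataFrame(
            {"lat": [-45.0], "lon": [0.0], "depth_m": [300.0], "month": [1],
             "fe_nmol_kg": [0.4]}
        )
        assert np.isnan(io.match_iron(-45.0, 0.0, pd.Timestamp("2016-01-15"), db))
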