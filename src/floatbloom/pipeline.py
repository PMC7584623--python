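"""Per-cast processing chain and the profiles -> climatology driver.

Order of operations per cast mirrors the processing conventions of the float
analysis: vertical median smoothing of the optical channels, bbp -> POC -> C_phyto,
deep-offset correction, negative screening, then the physical derivations (MLD,
euphotic depth, mixed-layer statistics) and the growth model.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import biomass, growth, profiles as prof, rates
from .errors import UnusableCastError
from .io import match_par_many
from .profiles import DerivedProfile, FloatProfile
from .vertical import layer_mean_inside

__all__ = ["PipelineConfig", "process_cast", "process_profiles", "run_pipeline"]

log = logging.getLogger("floatbloom")


@dataclass(frozen=True)
class PipelineConfig:
    median_window: int = 7
    mld_threshold: float = 0.03      # kg m-3
    mld_ref_depth: float = 10.0      # m
    max_gap_days: float = 20.0       # centered-difference pairing
    climatology_window_days: float = 60.0
    biomass_params: biomass.BiomassParams = field(default_factory=biomass.BiomassParams)
    growth_params: growth.GrowthParams = field(default_factory=growth.GrowthParams)


def _interp_gaps(depth, values):
    """Fill interior NaNs by linear interpolation in depth (for the light field only)."""
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.all() or not ok.any():
        return values
    return np.interp(depth, depth[ok], values[ok])


def process_cast(p: FloatProfile, config: PipelineConfig = PipelineConfig()) -> DerivedProfile:
    """Derive per-cast scalars from one float profile.

    Raises UnusableCastError for casts that cannot support the derivation (too few
    samples, no usable T/S, all-negative biomass).
    """
    if not p.is_usable():
        raise UnusableCastError(f"cast {p.float_id} @ {p.cast_time}: <5 valid samples above 200 m")

    bbp_s = prof.smooth_profile_vertical(p.bbp700, config.median_window)
    chl_s = prof.smooth_profile_vertical(p.chl, config.median_window)

    poc = biomass.poc_from_bbp(bbp_s, config.biomass_params)
    cp = biomass.cphyto_from_poc(poc, config.biomass_params)
    deep = biomass.correct_deep_offset(cp, p.depth, config.biomass_params.deep_ref_range)
    cp_screen = biomass.screen_negatives(deep.values)
    chl_screen = biomass.screen_negatives(chl_s)
    if cp_screen.all_negative:
        raise UnusableCastError(f"cast {p.float_id} @ {p.cast_time}: all C_phyto negative")
    cp_v, chl_v = cp_screen.values, chl_screen.values

    mld_est = prof.estimate_mld(p, config.mld_threshold, config.mld_ref_depth)
    mld = mld_est.mld

    out = DerivedProfile(
        float_id=p.float_id, cast_time=p.cast_time, latitude=p.latitude,
        longitude=p.longitude, under_ice=p.under_ice, mld=mld,
        mld_reached=mld_est.reached, par0=p.par0,
        flags={
            "n_neg_cphyto": cp_screen.n_removed,
            "n_neg_chl": chl_screen.n_removed,
            "deep_offset_corrected": deep.corrected,
            "deep_offset": deep.offset,
        },
    )

    zeu = np.nan
    if np.isfinite(p.par0):
        zres = prof.euphotic_depth(chl_v, p.depth, p.par0, config.growth_params)
        zeu = zres.zeu
        out.flags["dark"] = zres.dark
    out.zeu = zeu
    horizon = np.nanmax([mld, zeu])
    out.horizon = float(horizon)

    out.pbar, out.pint_mld, out.pint_horizon = prof.mixed_layer_stats(
        p.depth, cp_v, mld, horizon
    )

    if np.isfinite(p.par0) and p.par0 > 0:
        chl_fill = _interp_gaps(p.depth, chl_v)
        kd = growth.attenuation_from_chl(np.where(np.isfinite(chl_fill), chl_fill, 0.0),
                                         config.growth_params)
        light = growth.propagate_par(p.par0, kd, p.depth)
        mu = growth.division_rate_profile(chl_v, cp_v, light, config.growth_params, mld=mld)
        ok = np.isfinite(mu)
        if np.sum(ok & (p.depth < mld)) >= 2:
            out.mu_ml = layer_mean_inside(p.depth[ok], mu[ok], mld)
            cmax = growth.chlc_max_profile(light, mld, config.growth_params)
            chlc = np.where(ok, chl_v / cp_v, np.nan)
            nsi = growth.nutrient_saturation_index(chlc[ok], cmax[ok], config.growth_params)
            lsi = growth.light_saturation_index(light.par_z[ok], config.growth_params)
            out.nsi_ml = layer_mean_inside(p.depth[ok], nsi, mld)
            out.lsi_ml = layer_mean_inside(p.depth[ok], lsi, mld)
            out.par_ml = layer_mean_inside(p.depth, light.par_z, mld)
            both = ok & np.isfinite(cp_v)
            out.npp = growth.npp_profile(mu[both], cp_v[both], p.depth[both], horizon)
    return out


def process_profiles(
    profile_list: list[FloatProfile], config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Process every usable cast into a derived-profile table; logs drop counts."""
    rows, dropped = [], 0
    for p in profile_list:
        try:
            d = process_cast(p, config)
        except UnusableCastError as err:
            dropped += 1
            log.debug("dropped cast: %s", err)
            continue
        row = asdict(d)
        flags = row.pop("flags")
        row["n_neg_cphyto"] = flags.get("n_neg_cphyto", 0)
        row["n_neg_chl"] = flags.get("n_neg_chl", 0)
        rows.append(row)
    log.info("processed %d casts (%d dropped)", len(rows), dropped)
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["cast_time"] = pd.to_datetime(frame["cast_time"])
    return frame


def run_pipeline(
    profile_list: list[FloatProfile],
    par_field=None,
    config: PipelineConfig = PipelineConfig(),
):
    """Profiles (+ optional gridded PAR) -> derived table, r series, climatology."""
    if par_field is not None:
        match_par_many(profile_list, par_field)
    derived = process_profiles(profile_list, config)
    if derived.empty:
        raise UnusableCastError("no usable casts in input")
    rate_series = rates.build_rate_series(derived, max_gap=config.max_gap_days)
    climatology = rates.build_climatology(
        derived, rate_series, smoothing_window_days=config.climatology_window_days
    )
    return derived, rate_series, climatology
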