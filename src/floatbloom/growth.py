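"""Carbon-based productivity model (CbPM) adapted to float profiles.

The phytoplankton division rate at depth z is

    mu(z) = mu_max * NSI(z) * LSI(z)

with a nutrient saturation index diagnosed from photoacclimation of the Chl:C ratio,

    NSI(z) = (Chl:C(z) - Chl:C_mu0) / (Chl:C_max(PAR(z)) - Chl:C_mu0),   clamped to [0, 1]

and a light saturation index

    LSI(z) = 1 - exp(-lsi_rate * PAR(z)).

Within the mixed layer Chl:C_max is evaluated at the mean mixed-layer PAR
(cells circulating through a mixed layer acclimate to its average light, not to
the instantaneous light at their depth); below the mixed layer it uses local
PAR(z).

The underwater light field uses scalar PAR attenuated by a chlorophyll-dependent
diffuse coefficient Kd = kd_bias + kd_scale * Chl**kd_exponent (Morel-type
coefficients); layer-wise trapezoidal optical depths propagate surface PAR downward.
Chl:C_max is a declining function of local light,
Chl:C_max(PAR) = floor + (ceiling - floor) * exp(-decay * PAR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .vertical import layer_integral, layer_mean, layer_mean_inside

__all__ = [
    "GrowthParams",
    "LightField",
    "attenuation_from_chl",
    "propagate_par",
    "chlc_max_local",
    "nutrient_saturation_index",
    "light_saturation_index",
    "division_rate_profile",
    "npp_profile",
]


@dataclass(frozen=True)
class GrowthParams:
    """Tunables of the growth model.

    mu_max : maximum potential division rate (d-1)
    chlc_mu0 : Chl:C ratio at zero growth (mg Chl per mg C)
    lsi_rate : light-saturation rate constant ((E m-2 d-1)-1)
    chlc_max_floor / chlc_max_ceiling : bounds of the light-dependent maximum Chl:C
    chlc_max_decay : light decay of the maximum Chl:C ((E m-2 d-1)-1)
    kd_bias, kd_scale, kd_exponent : chlorophyll-dependent PAR attenuation (m-1)
    """

    mu_max: float = 2.0
    chlc_mu0: float = 3e-4
    lsi_rate: float = 5.0
    chlc_max_floor: float = 0.022
    chlc_max_ceiling: float = 0.045
    chlc_max_decay: float = 3.0
    kd_bias: float = 0.0166
    kd_scale: float = 0.0773
    kd_exponent: float = 0.672


@dataclass(frozen=True)
class LightField:
    """Depth-resolved scalar PAR: surface value, attenuation and PAR(z)."""

    par0: float
    depth: np.ndarray
    kd: np.ndarray
    par_z: np.ndarray


def attenuation_from_chl(chl, params: GrowthParams = GrowthParams()):
    """Diffuse PAR attenuation (m-1) per depth; pure-water floor at Chl = 0."""
    chl = np.asarray(chl, dtype=float)
    return params.kd_bias + params.kd_scale * np.clip(chl, 0.0, None) ** params.kd_exponent


def optical_depth(depth, kd):
    """Cumulative layer-wise trapezoidal optical depth from the surface.

    The shallowest sample's kd extends as a constant to 0 m.
    """
    depth = np.asarray(depth, dtype=float)
    kd = np.asarray(kd, dtype=float)
    tau = np.zeros_like(depth)
    if depth.size == 0:
        return tau
    tau[0] = kd[0] * depth[0]
    if depth.size > 1:
        layers = 0.5 * (kd[1:] + kd[:-1]) * np.diff(depth)
        tau[1:] = tau[0] + np.cumsum(layers)
    return tau


def propagate_par(par0, kd, depth) -> LightField:
    """Propagate surface PAR (E m-2 d-1) downward through the attenuation profile."""
    if par0 < 0:
        raise InvalidParameterError(f"surface PAR must be >= 0, got {par0}")
    depth = np.asarray(depth, dtype=float)
    kd = np.asarray(kd, dtype=float)
    par_z = par0 * np.exp(-optical_depth(depth, kd))
    return LightField(par0=float(par0), depth=depth, kd=kd, par_z=par_z)


def chlc_max_local(par_z, params: GrowthParams = GrowthParams()):
    """Maximum (nutrient-replete) Chl:C at the local light level."""
    par_z = np.asarray(par_z, dtype=float)
    span = params.chlc_max_ceiling - params.chlc_max_floor
    return params.chlc_max_floor + span * np.exp(-params.chlc_max_decay * par_z)


def nutrient_saturation_index(chlc, chlc_max, params: GrowthParams = GrowthParams()):
    """Nutrient saturation index in [0, 1] from the local Chl:C ratio."""
    chlc = np.asarray(chlc, dtype=float)
    chlc_max = np.asarray(chlc_max, dtype=float)
    if np.any(chlc_max <= params.chlc_mu0):
        raise InvalidParameterError("Chl:C_max must exceed Chl:C at mu=0")
    nsi = (chlc - params.chlc_mu0) / (chlc_max - params.chlc_mu0)
    return np.clip(nsi, 0.0, 1.0)


def light_saturation_index(par_z, params: GrowthParams = GrowthParams()):
    """Light saturation index 1 - exp(-lsi_rate * PAR), in [0, 1)."""
    par_z = np.asarray(par_z, dtype=float)
    if np.any(par_z[np.isfinite(par_z)] < 0):
        raise InvalidParameterError("PAR must be >= 0")
    return 1.0 - np.exp(-params.lsi_rate * par_z)


def chlc_max_profile(light: LightField, mld: float | None = None,
                     params: GrowthParams = GrowthParams()):
    """Acclimation reference Chl:C_max per depth.

    Mixed-layer depths use the mean mixed-layer PAR; depths below (or every depth
    when ``mld`` is None) use local PAR(z).
    """
    cmax = chlc_max_local(light.par_z, params)
    if mld is not None and mld > 0:
        par_ml = layer_mean_inside(light.depth, light.par_z, mld)
        cmax = np.where(light.depth <= mld, chlc_max_local(par_ml, params), cmax)
    return cmax


def division_rate_profile(chl, cphyto, light: LightField,
                          params: GrowthParams = GrowthParams(), mld: float | None = None):
    """Division rate mu(z) = mu_max * NSI(z) * LSI(z), d-1.

    Depths with missing or non-positive phytoplankton carbon get NaN (flagged upstream).
    """
    chl = np.asarray(chl, dtype=float)
    cphyto = np.asarray(cphyto, dtype=float)
    ok = np.isfinite(chl) & np.isfinite(cphyto) & (cphyto > 0)
    chlc = np.full_like(chl, np.nan)
    chlc[ok] = chl[ok] / cphyto[ok]
    cmax = chlc_max_profile(light, mld, params)
    mu = np.full_like(chl, np.nan)
    nsi = nutrient_saturation_index(chlc[ok], cmax[ok], params)
    lsi = light_saturation_index(light.par_z[ok], params)
    mu[ok] = params.mu_max * nsi * lsi
    return mu


def npp_profile(mu, cphyto, depth, horizon):
    """Vertically integrated NPP (mg C m-2 d-1): trapezoid of mu * C_phyto over [0, horizon]."""
    mu = np.asarray(mu, dtype=float)
    cphyto = np.asarray(cphyto, dtype=float)
    return layer_integral(depth, mu * cphyto, horizon)


def mixed_layer_mean(depth, values, mld):
    """Depth-weighted mean over the mixed layer (convenience re-export)."""
    return layer_mean(depth, values, mld)
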