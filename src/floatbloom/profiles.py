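"""Vertical-profile data model and per-cast physical derivations.

A :class:`FloatProfile` is one cast from a profiling float: a strictly increasing
depth grid with temperature, salinity, particulate backscatter at 700 nm and
chlorophyll, plus position/time and an under-ice flag. Derivations here are the
seven-point running-median vertical smoother, the density-threshold mixed layer
depth, the 1%-light euphotic depth and mixed-layer biomass statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import growth, seawater
from .errors import InvalidParameterError, UnusableCastError
from .vertical import layer_integral, layer_mean

__all__ = [
    "FloatProfile",
    "DerivedProfile",
    "MldEstimate",
    "EuphoticDepth",
    "smooth_profile_vertical",
    "estimate_mld",
    "euphotic_depth",
    "mixed_layer_stats",
]

MIN_SAMPLES_200M = 5  # usability: at least this many valid samples in the upper 200 m


@dataclass
class FloatProfile:
    """One vertical cast. Depths in m (positive down), strictly increasing."""

    float_id: str
    cast_time: pd.Timestamp
    latitude: float
    longitude: float
    depth: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    bbp700: np.ndarray
    chl: np.ndarray
    under_ice: bool = False
    par0: float = np.nan  # matched surface PAR (E m-2 d-1); NaN until matched

    def __post_init__(self):
        self.cast_time = pd.Timestamp(self.cast_time)
        for name in ("depth", "temperature", "salinity", "bbp700", "chl"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.depth.size and (np.any(np.diff(self.depth) <= 0) or self.depth[0] < 0):
            raise InvalidParameterError(
                f"depth grid must be strictly increasing and non-negative ({self.float_id})"
            )

    @property
    def has_position(self) -> bool:
        return bool(np.isfinite(self.latitude) and np.isfinite(self.longitude))

    def is_usable(self) -> bool:
        """A cast needs >= 5 valid bbp samples in the upper 200 m."""
        upper = self.depth <= 200.0
        return int(np.sum(upper & np.isfinite(self.bbp700))) >= MIN_SAMPLES_200M


@dataclass
class DerivedProfile:
    """Per-cast scalars derived from one FloatProfile."""

    float_id: str
    cast_time: pd.Timestamp
    latitude: float
    longitude: float
    under_ice: bool
    mld: float = np.nan
    mld_reached: bool = True
    zeu: float = np.nan
    horizon: float = np.nan
    pbar: float = np.nan          # mean mixed-layer C_phyto (mg C m-3)
    pint_mld: float = np.nan      # C_phyto integrated to the MLD (mg C m-2)
    pint_horizon: float = np.nan  # C_phyto integrated to max(MLD, Zeu)
    par0: float = np.nan
    par_ml: float = np.nan
    mu_ml: float = np.nan
    nsi_ml: float = np.nan
    lsi_ml: float = np.nan
    npp: float = np.nan
    flags: dict = field(default_factory=dict)


class MldEstimate(NamedTuple):
    mld: float
    reached: bool  # False when the density threshold was never exceeded


class EuphoticDepth(NamedTuple):
    zeu: float
    dark: bool  # True for zero surface PAR (polar night / under ice)


def smooth_profile_vertical(values, window: int = 7):
    """Centered running-median filter along depth.

    The window shrinks symmetrically near the profile ends (so a monotone series is a
    fixed point of the filter) and missing values are excluded from each window's
    median. Positions that are missing in the input stay missing.
    """
    if window % 2 == 0 or window < 3:
        raise InvalidParameterError(f"window must be odd and >= 3, got {window}")
    values = np.asarray(values, dtype=float)
    n = values.size
    out = np.full(n, np.nan)
    half = window // 2
    for i in range(n):
        h = min(half, i, n - 1 - i)
        seg = values[i - h : i + h + 1]
        if np.any(np.isfinite(seg)):
            out[i] = np.nanmedian(seg)
    out[~np.isfinite(values)] = np.nan
    return out


def estimate_mld(
    profile: FloatProfile,
    threshold: float = 0.03,
    ref_depth: float = 10.0,
) -> MldEstimate:
    """Mixed layer depth: shallowest depth where the potential density exceeds the
    density at ``ref_depth`` by ``threshold`` (kg m-3), linearly interpolated.

    Returns the deepest sampled depth with ``reached=False`` when the threshold is
    never exceeded (deep winter mixing / short cast).
    """
    z = profile.depth
    keep = np.isfinite(z) & np.isfinite(profile.temperature) & np.isfinite(profile.salinity)
    if np.sum(keep) < 2:
        raise UnusableCastError(f"no usable T/S pair in cast {profile.float_id}")
    z = z[keep]
    sig = seawater.sigma0(profile.salinity[keep], profile.temperature[keep])
    sig_ref = float(np.interp(ref_depth, z, sig))
    target = sig_ref + threshold
    below = z >= ref_depth
    zb, sb = z[below], sig[below]
    exceeded = np.nonzero(sb > target)[0]
    if exceeded.size == 0:
        return MldEstimate(float(z[-1]), reached=False)
    i = exceeded[0]
    if i == 0:
        return MldEstimate(float(zb[0]), reached=True)
    # linear interpolation between the bracketing samples
    frac = (target - sb[i - 1]) / (sb[i] - sb[i - 1])
    return MldEstimate(float(zb[i - 1] + frac * (zb[i] - zb[i - 1])), reached=True)


def euphotic_depth(
    chl,
    depth,
    surface_par: float,
    params: growth.GrowthParams = growth.GrowthParams(),
) -> EuphoticDepth:
    """Depth where downwelling PAR falls to 1% of its surface value.

    Uses the same chlorophyll-dependent attenuation as the growth model; capped at
    the deepest sample. Zero surface PAR returns 0 m with a darkness flag.
    """
    if surface_par < 0:
        raise InvalidParameterError(f"surface PAR must be >= 0, got {surface_par}")
    if surface_par == 0:
        return EuphoticDepth(0.0, dark=True)
    depth = np.asarray(depth, dtype=float)
    chl = np.asarray(chl, dtype=float)
    keep = np.isfinite(depth) & np.isfinite(chl)
    if not np.any(keep):
        raise UnusableCastError("no finite chlorophyll to compute attenuation")
    z, c = depth[keep], chl[keep]
    kd = growth.attenuation_from_chl(c, params)
    tau = growth.optical_depth(z, kd)
    tau_1pct = np.log(100.0)
    if tau[-1] < tau_1pct:
        return EuphoticDepth(float(z[-1]), dark=False)
    return EuphoticDepth(float(np.interp(tau_1pct, tau, z)), dark=False)


def mixed_layer_stats(depth, cphyto, mld: float, horizon: float | None = None):
    """Mixed-layer mean and vertically integrated phytoplankton carbon.

    Returns ``(pbar, pint_mld, pint_horizon)``: the depth-weighted trapezoidal mean
    over [0, mld], the integral to the MLD (the inventory used by the switching
    algorithm) and the integral to ``horizon`` (max of MLD and euphotic depth, the
    biomass-stock convention). Requires >= 2 valid samples above the MLD.
    """
    if mld <= 0:
        raise UnusableCastError(f"MLD must be positive, got {mld}")
    depth_arr = np.asarray(depth, dtype=float)
    cp = np.asarray(cphyto, dtype=float)
    good = np.isfinite(depth_arr) & np.isfinite(cp)
    if np.sum(good & (depth_arr < mld)) < 2:
        raise UnusableCastError("fewer than 2 valid C_phyto samples above the MLD")
    pint_mld = layer_integral(depth_arr[good], cp[good], mld)
    pbar = pint_mld / mld
    if horizon is None:
        horizon = mld
    pint_horizon = layer_integral(depth_arr[good], cp[good], max(horizon, mld))
    return float(pbar), float(pint_mld), float(pint_horizon)


def mixed_layer_mean(depth, values, mld):
    """Depth-weighted mean of any per-depth quantity over [0, MLD] (NaNs dropped)."""
    return layer_mean(depth, values, mld)
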