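"""Net biomass rate of change, time-series smoothing and annual climatologies.

The net rate of change r (d-1) between consecutive casts uses a switching
centered-difference: during mixed-layer shoaling it is computed from the mean
mixed-layer concentration P-bar, otherwise (deepening or stationary) from the
mixed-layer inventory, so that pure dilution on deepening and pure detrainment on
shoaling both yield r = 0 and r reflects the ecological balance mu - l only:

    r(t + dt/2) = (2/dt) * (X2 - X1) / (X2 + X1),   X = P-bar or integral(P).

Climatologies are day-of-year cycles (365 days, circular): observations are averaged
in weekly bins, smoothed with a centered 60-day circular window and linearly
interpolated to daily resolution. Feb 29 folds into day 365.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyClimatologyError
from .profiles import DerivedProfile

__all__ = [
    "RateObservation",
    "net_rate_of_change",
    "build_rate_series",
    "smooth_series",
    "WeeklyCycle",
    "weekly_climatology",
    "daily_from_weekly",
    "temporal_derivative",
    "Climatology",
    "build_climatology",
    "day_of_year_365",
]

WEEK_CENTERS = np.array([7 * w + 4 for w in range(51)] + [361.5])  # week 52 spans 8 days


@dataclass(frozen=True)
class RateObservation:
    float_id: str
    midpoint_time: pd.Timestamp
    r: float                 # d-1
    branch: str              # "concentration" (shoaling) or "inventory"
    dt: float                # days


def net_rate_of_change(first: DerivedProfile, second: DerivedProfile, max_gap: float = 20.0):
    """Switching centered-difference r between two consecutive casts of one float.

    Returns None (pair skipped) when the gap exceeds ``max_gap`` days, is non-positive,
    or the biomass sum in the selected branch vanishes.
    """
    dt = (second.cast_time - first.cast_time) / pd.Timedelta(days=1)
    if not 0 < dt <= max_gap:
        return None
    shoaling = (second.mld - first.mld) < 0
    if shoaling:
        x1, x2, branch = first.pbar, second.pbar, "concentration"
    else:
        x1, x2, branch = first.pint_mld, second.pint_mld, "inventory"
    if not (np.isfinite(x1) and np.isfinite(x2)) or (x1 + x2) == 0:
        return None
    r = (2.0 / dt) * (x2 - x1) / (x2 + x1)
    return RateObservation(
        float_id=first.float_id,
        midpoint_time=first.cast_time + pd.Timedelta(days=dt / 2),
        r=float(r),
        branch=branch,
        dt=float(dt),
    )


def build_rate_series(derived: pd.DataFrame, max_gap: float = 20.0) -> pd.DataFrame:
    """Per-float r series from a derived-profile table (one row per cast).

    The table needs columns float_id, cast_time, mld, pbar, pint_mld; each float's
    casts are paired in time order independently of the others.
    """
    rows = []
    for float_id, grp in derived.groupby("float_id", sort=False):
        grp = grp.sort_values("cast_time")
        recs = grp.to_dict("records")
        for a, b in zip(recs[:-1], recs[1:]):
            da = DerivedProfile(
                float_id=str(float_id), cast_time=pd.Timestamp(a["cast_time"]),
                latitude=a.get("latitude", np.nan), longitude=a.get("longitude", np.nan),
                under_ice=bool(a.get("under_ice", False)), mld=a["mld"],
                pbar=a["pbar"], pint_mld=a["pint_mld"],
            )
            db = DerivedProfile(
                float_id=str(float_id), cast_time=pd.Timestamp(b["cast_time"]),
                latitude=b.get("latitude", np.nan), longitude=b.get("longitude", np.nan),
                under_ice=bool(b.get("under_ice", False)), mld=b["mld"],
                pbar=b["pbar"], pint_mld=b["pint_mld"],
            )
            obs = net_rate_of_change(da, db, max_gap=max_gap)
            if obs is not None:
                rows.append(obs.__dict__)
    return pd.DataFrame(rows, columns=["float_id", "midpoint_time", "r", "branch", "dt"])


def _moving_mean_by_count(values: np.ndarray, n_points: int) -> np.ndarray:
    """Centered moving average over ``n_points`` samples, truncated at the ends."""
    n = values.size
    if n == 0 or n_points <= 1:
        return values.copy()
    half = n_points // 2
    cnt = np.concatenate([[0], np.cumsum(np.isfinite(values))])
    vals = np.where(np.isfinite(values), values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    num = csum[hi] - csum[lo]
    den = cnt[hi] - cnt[lo]
    out = np.full(n, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def smooth_series(times, values, window_days: float = 10.0, window_points: int = 500):
    """Two-stage smoother for a time-sorted irregular series.

    First a centered moving average over a ``window_days`` time window, then a
    centered moving average over ``window_points`` consecutive samples; both windows
    truncate at the series ends. Output is sampled at the input times.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        return v.copy()
    if np.any(np.diff(t) < 0):
        raise ValueError("series must be time-sorted")
    half = window_days / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    vals = np.where(np.isfinite(v), v, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    cnt = np.concatenate([[0], np.cumsum(np.isfinite(v))])
    num = csum[hi] - csum[lo]
    den = cnt[hi] - cnt[lo]
    stage1 = np.full(t.size, np.nan)
    ok = den > 0
    stage1[ok] = num[ok] / den[ok]
    return _moving_mean_by_count(stage1, window_points)


def day_of_year_365(times) -> np.ndarray:
    """Day-of-year on a fixed 365-day calendar; Feb 29 folds into day 365."""
    idx = pd.DatetimeIndex(pd.to_datetime(list(np.atleast_1d(times))))
    doy = idx.dayofyear.to_numpy().astype(int)
    leap = idx.is_leap_year
    feb29 = leap & (doy == 60)
    after = leap & (doy > 60)
    doy = doy - after.astype(int)
    doy[feb29] = 365
    return doy


@dataclass
class WeeklyCycle:
    """One variable's weekly-binned annual cycle and its daily interpolation."""

    centers: np.ndarray       # day-of-year of each weekly bin center (52,)
    weekly: np.ndarray        # smoothed weekly bin means (52,)
    weekly_raw: np.ndarray    # unsmoothed bin means (52,)
    n_obs: np.ndarray         # observations per bin (52,)
    daily: np.ndarray         # 365 daily values, circular linear interpolation


def _circular_window_mean(centers, values, window_days):
    """Centered circular moving average over a day window on irregular knots."""
    out = np.full(values.size, np.nan)
    half = window_days / 2.0
    for i, c in enumerate(centers):
        d = np.abs(centers - c)
        d = np.minimum(d, 365.0 - d)
        sel = (d <= half) & np.isfinite(values)
        if np.any(sel):
            out[i] = np.mean(values[sel])
    return out


def daily_from_weekly(centers, weekly) -> np.ndarray:
    """Circular linear interpolation of weekly knots to days 1..365."""
    centers = np.asarray(centers, dtype=float)
    weekly = np.asarray(weekly, dtype=float)
    ok = np.isfinite(weekly)
    if not np.any(ok):
        raise EmptyClimatologyError("no populated weekly bins")
    c, v = centers[ok], weekly[ok]
    c_ext = np.concatenate([c - 365.0, c, c + 365.0])
    v_ext = np.concatenate([v, v, v])
    return np.interp(np.arange(1, 366, dtype=float), c_ext, v_ext)


def weekly_climatology(day_of_year, values, smoothing_window_days: float = 60.0) -> WeeklyCycle:
    """Weekly-binned, circularly smoothed, daily-interpolated annual climatology.

    Observations tagged by (folded) day-of-year are averaged into 52 weekly bins
    (week 53 days fold into week 52), smoothed with a centered circular window of
    ``smoothing_window_days``, and linearly interpolated to 365 daily values.
    Fewer than 26 populated bins triggers a low-coverage warning.
    """
    doy = np.asarray(day_of_year, dtype=int)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(v) & (doy >= 1) & (doy <= 365)
    doy, v = doy[keep], v[keep]
    week = np.minimum((doy - 1) // 7, 51)
    means = np.full(52, np.nan)
    n_obs = np.zeros(52, dtype=int)
    for w in range(52):
        sel = week == w
        n_obs[w] = int(np.sum(sel))
        if n_obs[w]:
            means[w] = float(np.mean(v[sel]))
    if not np.any(np.isfinite(means)):
        raise EmptyClimatologyError("all weekly bins empty")
    if int(np.sum(np.isfinite(means))) < 26:
        warnings.warn("fewer than 26 of 52 weekly bins populated; low-coverage climatology")
    smoothed = _circular_window_mean(WEEK_CENTERS, means, smoothing_window_days)
    daily = daily_from_weekly(WEEK_CENTERS, smoothed)
    return WeeklyCycle(
        centers=WEEK_CENTERS.copy(), weekly=smoothed, weekly_raw=means, n_obs=n_obs, daily=daily
    )


def temporal_derivative(cycle) -> np.ndarray:
    """Centered circular difference of a 365-day cycle, units per day."""
    x = np.asarray(cycle, dtype=float)
    return (np.roll(x, -1) - np.roll(x, 1)) / 2.0


@dataclass
class Climatology:
    """Day-of-year-resolved mean annual cycles for one region.

    ``daily`` is a DataFrame indexed by day_of_year 1..365 with one column per
    variable; ``weekly`` holds the raw weekly bin means and per-bin counts.
    """

    daily: pd.DataFrame
    weekly: pd.DataFrame

    def __getitem__(self, var: str) -> np.ndarray:
        return self.daily[var].to_numpy()


def build_climatology(
    derived: pd.DataFrame,
    rate_series: pd.DataFrame,
    smoothing_window_days: float = 60.0,
    variables=("pbar", "pint_mld", "pint_horizon", "mu_ml", "mld", "horizon", "par_ml"),
) -> Climatology:
    """Pooled weekly climatology of derived-cast variables plus the r series."""
    daily = {}
    weekly = {"center_day": WEEK_CENTERS}
    doy = day_of_year_365(derived["cast_time"])
    for var in variables:
        if var not in derived.columns:
            continue
        cyc = weekly_climatology(doy, derived[var].to_numpy(), smoothing_window_days)
        name = {"mu_ml": "mu"}.get(var, var)
        daily[name] = cyc.daily
        weekly[name] = cyc.weekly_raw
        weekly[f"n_obs_{name}"] = cyc.n_obs
    if len(rate_series):
        rdoy = day_of_year_365(rate_series["midpoint_time"])
        cyc = weekly_climatology(rdoy, rate_series["r"].to_numpy(), smoothing_window_days)
        daily["r"] = cyc.daily
        weekly["r"] = cyc.weekly_raw
        weekly["n_obs_r"] = cyc.n_obs
    daily_df = pd.DataFrame(daily, index=pd.RangeIndex(1, 366, name="day_of_year"))
    return Climatology(daily=daily_df, weekly=pd.DataFrame(weekly))
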