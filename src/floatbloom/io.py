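"""Readers/writers for the profile dialects and the PAR / iron matchup engines.

Two on-disk dialects are supported for float profiles:

* a flat CSV, one row per depth sample, columns float_id, time (ISO-8601), lat, lon,
  depth_m, temp_C, psal, bbp700_m-1, chl_mg_m-3, under_ice (0/1);
* an Argo-like NetCDF, one file per float (or one multi-float file), dimensions
  N_PROF x N_LEVELS, variables PRES/TEMP/PSAL/BBP700/CHLA plus JULD, LATITUDE,
  LONGITUDE and POSITION_QC (9 = position missing, used as the under-ice proxy).

NetCDF goes through xarray's scipy backend (NetCDF-3).

Matchup rules: PAR is the same-day nearest grid pixel; dissolved iron is the mean of
all database points within a 500 km haversine radius, the same calendar month (any
year) and the upper 200 m. A missing position never matches anything.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .profiles import FloatProfile

__all__ = [
    "profiles_to_frame",
    "frame_to_profiles",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_profiles_netcdf",
    "read_profiles_netcdf",
    "write_climatology_csv",
    "write_climatology_netcdf",
    "haversine_km",
    "match_par",
    "match_par_many",
    "par_coverage",
    "match_iron",
    "write_run_summary",
]

CSV_COLUMNS = [
    "float_id", "time", "lat", "lon", "depth_m", "temp_C", "psal",
    "bbp700_m-1", "chl_mg_m-3", "under_ice",
]

EARTH_RADIUS_KM = 6371.0


def profiles_to_frame(profiles: list[FloatProfile]) -> pd.DataFrame:
    """Flat one-row-per-depth-sample table in the CSV dialect's column order."""
    parts = []
    for p in profiles:
        parts.append(
            pd.DataFrame(
                {
                    "float_id": p.float_id,
                    "time": p.cast_time.isoformat(),
                    "lat": p.latitude,
                    "lon": p.longitude,
                    "depth_m": p.depth,
                    "temp_C": p.temperature,
                    "psal": p.salinity,
                    "bbp700_m-1": p.bbp700,
                    "chl_mg_m-3": p.chl,
                    "under_ice": int(p.under_ice),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)[CSV_COLUMNS]


def frame_to_profiles(frame: pd.DataFrame) -> list[FloatProfile]:
    profiles = []
    for (fid, time), grp in frame.groupby(["float_id", "time"], sort=True):
        grp = grp.sort_values("depth_m")
        profiles.append(
            FloatProfile(
                float_id=str(fid),
                cast_time=pd.Timestamp(time),
                latitude=float(grp["lat"].iloc[0]),
                longitude=float(grp["lon"].iloc[0]),
                depth=grp["depth_m"].to_numpy(),
                temperature=grp["temp_C"].to_numpy(),
                salinity=grp["psal"].to_numpy(),
                bbp700=grp["bbp700_m-1"].to_numpy(),
                chl=grp["chl_mg_m-3"].to_numpy(),
                under_ice=bool(grp["under_ice"].iloc[0]),
            )
        )
    profiles.sort(key=lambda p: (p.float_id, p.cast_time))
    return profiles


def write_profiles_csv(profiles: list[FloatProfile], path) -> None:
    # pandas' default shortest-repr float formatting round-trips float64 exactly,
    # keeping the dialect lossless
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles_csv(path) -> list[FloatProfile]:
    # round_trip parsing: the default fast float parser can be one ulp off
    return frame_to_profiles(pd.read_csv(path, float_precision="round_trip"))


def write_profiles_netcdf(profiles: list[FloatProfile], path) -> None:
    """Argo-like N_PROF x N_LEVELS layout; ragged casts padded with NaN."""
    n_prof = len(profiles)
    n_lev = max(p.depth.size for p in profiles)
    def padded(attr):
        out = np.full((n_prof, n_lev), np.nan)
        for i, p in enumerate(profiles):
            out[i, : p.depth.size] = getattr(p, attr)
        return out
    juld = np.array([p.cast_time.to_datetime64() for p in profiles])
    ds = xr.Dataset(
        {
            "PRES": (("N_PROF", "N_LEVELS"), padded("depth")),
            "TEMP": (("N_PROF", "N_LEVELS"), padded("temperature")),
            "PSAL": (("N_PROF", "N_LEVELS"), padded("salinity")),
            "BBP700": (("N_PROF", "N_LEVELS"), padded("bbp700")),
            "CHLA": (("N_PROF", "N_LEVELS"), padded("chl")),
            "JULD": (("N_PROF",), juld),
            "LATITUDE": (("N_PROF",), np.array([p.latitude for p in profiles])),
            "LONGITUDE": (("N_PROF",), np.array([p.longitude for p in profiles])),
            "POSITION_QC": (("N_PROF",), np.array([9 if p.under_ice else 1 for p in profiles])),
            "FLOAT_ID": (("N_PROF",), np.array([p.float_id for p in profiles], dtype="S16")),
        }
    )
    ds.to_netcdf(path, engine="scipy")


def read_profiles_netcdf(path) -> list[FloatProfile]:
    with xr.open_dataset(path, engine="scipy") as ds:
        profiles = []
        for i in range(ds.sizes["N_PROF"]):
            depth = ds["PRES"].values[i]
            keep = np.isfinite(depth)
            fid = ds["FLOAT_ID"].values[i]
            if isinstance(fid, bytes):
                fid = fid.decode().strip("\x00").strip()
            profiles.append(
                FloatProfile(
                    float_id=str(fid),
                    cast_time=pd.Timestamp(ds["JULD"].values[i]),
                    latitude=float(ds["LATITUDE"].values[i]),
                    longitude=float(ds["LONGITUDE"].values[i]),
                    depth=depth[keep],
                    temperature=ds["TEMP"].values[i][keep],
                    salinity=ds["PSAL"].values[i][keep],
                    bbp700=ds["BBP700"].values[i][keep],
                    chl=ds["CHLA"].values[i][keep],
                    under_ice=int(ds["POSITION_QC"].values[i]) == 9,
                )
            )
    return profiles


def write_climatology_csv(climatology, path) -> None:
    climatology.daily.to_csv(path)


def write_climatology_netcdf(climatology, path) -> None:
    ds = xr.Dataset.from_dataframe(climatology.daily)
    ds.to_netcdf(path, engine="scipy")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance (km), spherical Earth of radius 6371 km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, np.asarray(lat2, dtype=float), np.asarray(lon2, dtype=float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def match_par(latitude, longitude, time, par_field: xr.Dataset) -> float:
    """Same-day nearest-pixel surface PAR; NaN for missing positions or empty cells."""
    if not (np.isfinite(latitude) and np.isfinite(longitude)):
        return float("nan")
    day = pd.Timestamp(time).normalize()
    times = pd.DatetimeIndex(par_field["time"].values).normalize()
    sel = np.nonzero(times == day)[0]
    if sel.size == 0:
        return float("nan")
    cell = par_field["par"].isel(time=sel[0]).sel(lat=latitude, lon=longitude, method="nearest")
    return float(cell.values)


def match_par_many(profiles: list[FloatProfile], par_field: xr.Dataset) -> list[FloatProfile]:
    """Attach PAR matchups to casts in place; returns the same list."""
    for p in profiles:
        p.par0 = match_par(p.latitude, p.longitude, p.cast_time, par_field)
    return profiles


def par_coverage(profiles: list[FloatProfile]) -> float:
    """Fraction of casts with a valid PAR matchup."""
    if not profiles:
        return float("nan")
    return float(np.mean([np.isfinite(p.par0) for p in profiles]))


def match_iron(
    latitude,
    longitude,
    time,
    iron_db: pd.DataFrame,
    radius_km: float = 500.0,
    max_depth: float = 200.0,
) -> float:
    """Mean dissolved iron (nmol kg-1) over all qualifying database points.

    Qualifying: haversine distance <= radius_km (strict ball), same calendar month
    as the cast (any year), sample depth <= max_depth. NaN when none qualify or the
    position is missing.
    """
    if not (np.isfinite(latitude) and np.isfinite(longitude)) or iron_db.empty:
        return float("nan")
    month = pd.Timestamp(time).month
    cand = iron_db[(iron_db["month"] == month) & (iron_db["depth_m"] <= max_depth)]
    if cand.empty:
        return float("nan")
    dist = haversine_km(latitude, longitude, cand["lat"].to_numpy(), cand["lon"].to_numpy())
    sel = dist <= radius_km
    if not np.any(sel):
        return float("nan")
    return float(cand.loc[sel, "fe_nmol_kg"].mean())


def write_run_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
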