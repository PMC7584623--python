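"""Bloom phenology: initiation/termination/r-minimum, magnitude, zones, ice cover.

The blooming phase is the period of the annual cycle where the net biomass rate of
change r is positive. Bloom initiation (BI) is the negative-to-positive sign change
of r that starts the longest contiguous r > 0 run (circularly); bloom termination
(BT) is the positive-to-negative change ending that run; the r-minimum (rM) is the
most negative r within the r < 0 phase immediately preceding BI, i.e. the moment of
peak net biomass loss in autumn.

Bloom magnitude is the summer (Nov-Jan) minus winter (May-Jul) mean of mixed-layer
phytoplankton carbon. Zones default to Southern Ocean latitude bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BloomEvents",
    "detect_bloom_events",
    "bloom_magnitude",
    "ZoneDefinition",
    "DEFAULT_ZONES",
    "assign_zone",
    "under_ice_fraction",
]

# fixed 365-day calendar windows (day-of-year, inclusive)
WINTER_WINDOW = (121, 212)   # May 1 - Jul 31
SUMMER_WINDOW = (305, 31)    # Nov 1 - Jan 31, wraps the year boundary


@dataclass
class BloomEvents:
    """Phenology of one 365-day r cycle. Day fields are None when no bloom exists."""

    bi_day: int | None
    bt_day: int | None
    rm_day: int | None
    blooming_mask: np.ndarray
    runs: list = field(default_factory=list)  # all (start_day, end_day, length) r>0 runs
    diagnostic: str = ""


def _circular_runs(mask: np.ndarray):
    """Contiguous True runs of a circular boolean mask as (start, end, length), 1-based."""
    n = mask.size
    if mask.all() or not mask.any():
        return []
    # rotate so position 0 is False, then find plain runs
    start0 = int(np.argmin(mask))
    rolled = np.roll(mask, -start0)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], rolled.view(np.int8), [0]])))
    runs = []
    for a, b in zip(edges[::2], edges[1::2]):
        start = (a + start0) % n
        end = (b - 1 + start0) % n
        runs.append((start + 1, end + 1, b - a))  # 1-based days
    return runs


def detect_bloom_events(r_clim) -> BloomEvents:
    """Locate BI, BT and rM on a 365-day circular cycle of r.

    When r never changes sign there is no bloom to delimit: all day fields are None
    and the diagnostic says why. With several r > 0 runs, the longest is the primary
    bloom; all runs are reported.
    """
    r = np.asarray(r_clim, dtype=float)
    if r.size != 365:
        raise ValueError(f"expected a 365-day cycle, got {r.size}")
    mask = r > 0
    if mask.all():
        return BloomEvents(None, None, None, mask, [], "r always positive; no bloom cycle")
    if not mask.any():
        return BloomEvents(None, None, None, mask, [], "r never positive; no bloom cycle")
    runs = sorted(_circular_runs(mask), key=lambda t: t[2], reverse=True)
    bi, bt, _ = runs[0]
    # negative phase immediately preceding BI (circular): walk back from bi-1
    day = bi - 2  # 0-based index of the day before BI
    phase = []
    for _ in range(365):
        idx = day % 365
        if mask[idx]:
            break
        phase.append(idx)
        day -= 1
    rm_day = None
    if phase:
        phase = np.array(phase)
        rm_idx = phase[np.argmin(r[phase])]
        if r[rm_idx] < 0:
            rm_day = int(rm_idx + 1)
    return BloomEvents(int(bi), int(bt), rm_day, mask, runs)


def _in_window(doy: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    doy = np.asarray(doy, dtype=int)
    if lo <= hi:
        return (doy >= lo) & (doy <= hi)
    return (doy >= lo) | (doy <= hi)


def bloom_magnitude(day_of_year, pbar) -> float:
    """Summer (Nov 1 - Jan 31) minus winter (May 1 - Jul 31) mean biomass (mg C m-3).

    NaN with both-seasons coverage missing: returns NaN when either window has no
    observation (undefined-magnitude flag).
    """
    doy = np.asarray(day_of_year, dtype=int)
    v = np.asarray(pbar, dtype=float)
    ok = np.isfinite(v)
    winter = ok & _in_window(doy, WINTER_WINDOW)
    summer = ok & _in_window(doy, SUMMER_WINDOW)
    if not winter.any() or not summer.any():
        return float("nan")
    return float(np.mean(v[summer]) - np.mean(v[winter]))


@dataclass(frozen=True)
class ZoneDefinition:
    """A latitude-band zone: south-of ``lat_north`` down to (exclusive) ``lat_south``."""

    name: str
    lat_north: float  # inclusive northern edge (degrees north, negative south)
    lat_south: float  # exclusive southern edge

    def contains(self, lat: float) -> bool:
        return self.lat_south < lat <= self.lat_north


DEFAULT_ZONES = (
    ZoneDefinition("STZ", -30.0, -40.0),
    ZoneDefinition("SAZ", -40.0, -50.0),
    ZoneDefinition("PAZ", -50.0, -60.0),
    ZoneDefinition("SIZ", -60.0, -90.0),
)


def assign_zone(latitude, longitude=np.nan, zones=DEFAULT_ZONES) -> str | None:
    """Zone name for a position; None for missing positions ('unzoned'), and None
    with a domain rejection for latitudes north of 30 degrees S."""
    if not np.isfinite(latitude):
        return None
    if latitude > -30.0:
        return None  # outside the Southern Ocean domain
    for zone in zones:
        if zone.contains(latitude):
            return zone.name
    return None


def under_ice_fraction(under_ice_flags) -> tuple[float, bool]:
    """Fraction of casts in a bin flagged under ice, and whether the bin counts as
    under-ice (fraction >= 0.5, inclusive)."""
    flags = np.asarray(under_ice_flags, dtype=bool)
    if flags.size == 0:
        return float("nan"), False
    frac = float(np.mean(flags))
    return frac, frac >= 0.5
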