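"""Optical proxies to carbon: bbp(700) -> POC -> phytoplankton carbon.

POC (mg m-3) comes from a linear empirical fit to particulate backscatter at 700 nm,
POC = 3.12e4 * bbp + 3.0; phytoplankton carbon is a fixed fraction of POC,
C_phyto = 0.19 * POC. Each C_phyto profile is corrected by subtracting its mean
value in a deep reference layer (900-2000 m), so the profile asymptotes to zero at
depth, and negative values are then masked before entering the growth model.

The fit uncertainties (+-2.47e3 on the slope, +-6.8 on the intercept, +-8.7 on
C_phyto) are carried as metadata only; the analysis runs on point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "BiomassParams",
    "poc_from_bbp",
    "cphyto_from_poc",
    "bbp_from_cphyto",
    "correct_deep_offset",
    "screen_negatives",
]


@dataclass(frozen=True)
class BiomassParams:
    poc_slope: float = 3.12e4          # mg m-3 per m-1
    poc_intercept: float = 3.0         # mg m-3
    cphyto_fraction: float = 0.19
    deep_ref_range: tuple[float, float] = (900.0, 2000.0)
    # fit uncertainties, metadata only (not propagated)
    poc_slope_err: float = 2.47e3
    poc_intercept_err: float = 6.8
    cphyto_err: float = 8.7

    def __post_init__(self):
        if self.poc_slope <= 0:
            raise ValueError("poc_slope must be positive")
        if not 0 < self.cphyto_fraction < 1:
            raise ValueError("cphyto_fraction must be in (0, 1)")
        lo, hi = self.deep_ref_range
        if not 0 < lo < hi:
            raise ValueError("deep_ref_range must be ordered and positive")


def poc_from_bbp(bbp700, params: BiomassParams = BiomassParams()):
    """Particulate organic carbon (mg m-3) from bbp(700) (m-1), elementwise."""
    return params.poc_slope * np.asarray(bbp700, dtype=float) + params.poc_intercept


def cphyto_from_poc(poc, params: BiomassParams = BiomassParams()):
    """Phytoplankton carbon (mg C m-3) as a fixed fraction of POC."""
    return params.cphyto_fraction * np.asarray(poc, dtype=float)


def bbp_from_cphyto(cphyto, params: BiomassParams = BiomassParams()):
    """Exact inverse of the bbp -> POC -> C_phyto chain (synthetic-data contract)."""
    poc = np.asarray(cphyto, dtype=float) / params.cphyto_fraction
    return (poc - params.poc_intercept) / params.poc_slope


class DeepOffsetResult(NamedTuple):
    values: np.ndarray
    offset: float        # subtracted deep mean (NaN when no reference samples)
    corrected: bool      # False -> no sample in the reference layer, passed through


def correct_deep_offset(cphyto, depth, deep_ref_range=(900.0, 2000.0)) -> DeepOffsetResult:
    """Subtract the mean 900-2000 m concentration from the whole profile.

    Profiles with no sample in the reference layer pass through unchanged with a
    no-deep-reference flag. Idempotent: the corrected deep mean is zero.
    """
    cphyto = np.asarray(cphyto, dtype=float)
    depth = np.asarray(depth, dtype=float)
    lo, hi = deep_ref_range
    in_ref = (depth >= lo) & (depth <= hi) & np.isfinite(cphyto)
    if not np.any(in_ref):
        return DeepOffsetResult(cphyto.copy(), np.nan, corrected=False)
    offset = float(np.mean(cphyto[in_ref]))
    return DeepOffsetResult(cphyto - offset, offset, corrected=True)


class ScreenResult(NamedTuple):
    values: np.ndarray   # negatives masked to NaN, same length
    n_removed: int
    all_negative: bool   # degenerate cast: nothing usable left


def screen_negatives(values) -> ScreenResult:
    """Mask negative concentrations (they would produce spurious growth-model output)."""
    values = np.asarray(values, dtype=float)
    neg = np.isfinite(values) & (values < 0)
    out = values.copy()
    out[neg] = np.nan
    n_finite = int(np.sum(np.isfinite(values)))
    return ScreenResult(out, int(np.sum(neg)), all_negative=n_finite > 0 and int(np.sum(neg)) == n_finite)
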