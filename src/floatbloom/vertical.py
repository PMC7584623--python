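"""Trapezoidal vertical integrals and means on irregular depth grids.

Conventions shared by the profile and growth modules:

* the shallowest valid sample is extended as a constant to 0 m (float casts start at
  ~5-7 m; no surface gradient is fabricated);
* the deepest valid sample is extended as a constant if the integration bottom lies
  below it;
* a point is linearly interpolated at the integration bottom so the integral ends
  exactly there;
* missing (NaN) samples are dropped before integrating.
"""

from __future__ import annotations

import numpy as np

from .errors import UnusableCastError

__all__ = ["layer_integral", "layer_mean", "layer_mean_inside", "dropna_pair"]


def dropna_pair(depth, values):
    """Return (depth, values) with rows containing NaN in either array removed."""
    depth = np.asarray(depth, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(depth) & np.isfinite(values)
    return depth[keep], values[keep]


def _prepare(depth, values, z_bottom):
    depth, values = dropna_pair(depth, values)
    if z_bottom <= 0:
        raise UnusableCastError(f"integration bottom must be positive, got {z_bottom}")
    if np.sum(depth < z_bottom) < 2 and depth.size < 2:
        raise UnusableCastError("need at least 2 valid samples for a vertical integral")
    # surface extension
    if depth[0] > 0:
        depth = np.concatenate([[0.0], depth])
        values = np.concatenate([[values[0]], values])
    # bottom extension / interpolation point at z_bottom
    if depth[-1] < z_bottom:
        depth = np.concatenate([depth, [z_bottom]])
        values = np.concatenate([values, [values[-1]]])
    elif z_bottom not in depth:
        v_bot = np.interp(z_bottom, depth, values)
        keep = depth < z_bottom
        depth = np.concatenate([depth[keep], [z_bottom]])
        values = np.concatenate([values[keep], [v_bot]])
    else:
        keep = depth <= z_bottom
        depth, values = depth[keep], values[keep]
    return depth, values


def layer_integral(depth, values, z_bottom):
    """Trapezoidal integral of ``values`` over [0, z_bottom] (units: value * m)."""
    depth, values = _prepare(depth, values, z_bottom)
    return float(np.trapezoid(values, depth))


def layer_mean(depth, values, z_bottom):
    """Depth-weighted (trapezoidal) mean of ``values`` over [0, z_bottom]."""
    return layer_integral(depth, values, z_bottom) / float(z_bottom)


def layer_mean_inside(depth, values, z_bottom):
    """Depth-weighted mean over [0, z_bottom] using only in-layer samples.

    The deepest sample at or above ``z_bottom`` extends as a constant to the
    boundary instead of interpolating across it. Used for mixed-layer means of
    water-mass properties (growth rate, saturation indices, light): water just
    below the layer base is stratified and systematically different, so values
    from below must not leak into the layer mean.
    """
    depth, values = dropna_pair(depth, values)
    inside = depth <= z_bottom
    if np.sum(inside) < 2:
        raise UnusableCastError("fewer than 2 valid samples inside the layer")
    d, v = depth[inside], values[inside]
    if d[0] > 0:
        d = np.concatenate([[0.0], d])
        v = np.concatenate([[v[0]], v])
    if d[-1] < z_bottom:
        d = np.concatenate([d, [z_bottom]])
        v = np.concatenate([v, [v[-1]]])
    return float(np.trapezoid(v, d)) / float(z_bottom)
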