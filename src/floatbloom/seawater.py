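"""Surface-referenced seawater density (EOS-80).

Potential density here is the in-situ density evaluated at 0 dbar (sigma-theta with the
adiabatic correction neglected, consistent with treating pressure in dbar as depth in m).
The polynomial is the UNESCO 1983 / Millero & Poisson (1981) one-atmosphere equation of
state, valid for -2 <= T <= 40 degC and 0 <= S <= 42.
"""

from __future__ import annotations

import numpy as np

__all__ = ["density_surface", "sigma0", "salinity_for_density"]


def density_surface(salinity, temperature):
    """Seawater density (kg m-3) at 0 dbar from practical salinity and temperature (degC)."""
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s * np.sqrt(np.abs(s)) + c * s**2


def sigma0(salinity, temperature):
    """Potential density anomaly (kg m-3) referenced to the surface."""
    return density_surface(salinity, temperature) - 1000.0


def salinity_for_density(target_sigma0, temperature, s_init=34.0, n_iter=4):
    """Invert sigma0 for salinity at fixed temperature (Newton iterations).

    Used by the synthetic generator so that emitted T/S reproduce a prescribed density
    profile through the same equation of state the MLD estimator applies.
    """
    s = np.full_like(np.asarray(target_sigma0, dtype=float), float(s_init))
    t = np.asarray(temperature, dtype=float)
    for _ in range(n_iter):
        f = sigma0(s, t) - target_sigma0
        ds = 1e-4
        dfds = (sigma0(s + ds, t) - sigma0(s - ds, t)) / (2 * ds)
        s = s - f / dfds
    return s
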