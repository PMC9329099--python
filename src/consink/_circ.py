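"""Weighted circular statistics on binned direction distributions.

All public analysis code works in degrees; these helpers accept degrees and
do the radian conversion internally.  The Rayleigh test follows the classic
weighted formulation with the bin-width correction factor
``d/2 / sin(d/2)`` applied to the resultant length when the data are binned.
"""
from __future__ import annotations

import numpy as np


def wrap_360(angle_deg):
    """Wrap angles into [0, 360)."""
    return np.asarray(angle_deg) % 360.0


def wrap_180(angle_deg):
    """Wrap angles into (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float) % 360.0
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    a[a > 180.0] -= 360.0
    return a[0] if scalar else a


def resultant(angles_deg, weights=None, axis=-1):
    """Mean resultant length and circular mean direction (degrees).

    Returns ``(mrl, mean_deg)``; both are NaN where the total weight is zero.
    """
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if weights is None:
        weights = np.ones_like(ang)
    w = np.asarray(weights, dtype=float)
    c = np.sum(w * np.cos(ang), axis=axis)
    s = np.sum(w * np.sin(ang), axis=axis)
    n = np.sum(w, axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        mrl = np.hypot(c, s) / n
    mean = np.rad2deg(np.arctan2(s, c))
    return mrl, wrap_180(mean)


def rayleigh_test(angles_deg, weights=None, bin_width_deg=None):
    """Weighted Rayleigh test of circular non-uniformity.

    Parameters
    ----------
    angles_deg : array
        Sample angles or bin centres.
    weights : array, optional
        Non-negative weights (e.g. a corrected tuning distribution).
    bin_width_deg : float, optional
        When the angles are bin centres of a binned distribution, applies the
        standard correction ``d/2 / sin(d/2)`` to the resultant length.

    Returns
    -------
    (z, p) : floats
        Rayleigh statistic and p-value (finite-n corrected approximation).
    """
    mrl, _ = resultant(angles_deg, weights)
    if weights is None:
        n = float(np.size(angles_deg))
    else:
        n = float(np.sum(weights))
    if bin_width_deg is not None:
        d = np.deg2rad(bin_width_deg)
        mrl = mrl * (d / 2.0) / np.sin(d / 2.0)
    R = n * mrl
    z = R**2 / n
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - R**2)) - (1.0 + 2.0 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def circular_interp(t, tp, angles_deg):
    """Interpolate an angular time series along the shortest arc (degrees)."""
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(np.asarray(angles_deg, float))))
    return wrap_360(np.interp(t, tp, unwrapped))


def circular_mean(angles_deg, weights=None, axis=-1):
    """Circular mean direction in (-180, 180]."""
    return resultant(angles_deg, weights, axis=axis)[1]


def angular_difference(a_deg, b_deg):
    """Signed smallest difference a - b in (-180, 180]."""
    return wrap_180(np.asarray(a_deg, float) - np.asarray(b_deg, float))
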