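"""Small circular-statistics helpers shared across the package.

All public interfaces use degrees in [0, 360); radians stay internal.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_deg",
    "circ_dist_deg",
    "circ_mean_deg",
    "vm_shape",
    "vm_pdf_deg",
    "kappa_from_fwhm",
    "fwhm_from_kappa",
]


def wrap_deg(angle):
    """Map an angle (scalar or array) to [0, 360).

    Guards the half-open bound: for tiny negative inputs the float modulo
    rounds to exactly 360, which is folded back to 0.
    """
    out = np.asarray(angle, dtype=float) % 360.0
    return np.where(out == 360.0, 0.0, out)


def circ_dist_deg(a, b):
    """Absolute circular distance between two angles in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def circ_mean_deg(angles_deg, weights=None):
    """Circular mean of angles in degrees, in [0, 360)."""
    t = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if weights is None:
        weights = np.ones_like(t)
    z = np.sum(np.asarray(weights, dtype=float) * np.exp(1j * t))
    return float(np.rad2deg(np.angle(z)) % 360.0)


def vm_shape(theta_deg, mu_deg, kappa, period180=False):
    """Peak-normalized von Mises tuning shape, exp(kappa*(cos(d)-1)).

    ``d`` is the circular offset from ``mu_deg``; with ``period180`` the
    offset is doubled, producing the axial (orientation) variant with two
    equal peaks 180 degrees apart.  The value at the peak is exactly 1, so
    a separate amplitude parameter carries the response scale.
    """
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - mu_deg)
    if period180:
        d = 2.0 * d
    return np.exp(kappa * (np.cos(d) - 1.0))


def vm_pdf_deg(theta_deg, mu_deg, kappa):
    """Von Mises probability density (over radians) evaluated at degrees.

    Integrates to 1 over one full cycle of the angle in radians; kappa=0
    degenerates to the uniform density 1/(2*pi).
    """
    from scipy.special import i0

    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - mu_deg)
    return np.exp(kappa * np.cos(d)) / (2.0 * np.pi * i0(kappa))


_LN2 = float(np.log(2.0))


def kappa_from_fwhm(fwhm_deg):
    """Concentration of the peak-normalized von Mises with a given FWHM.

    Inverts ``fwhm = 2*arccos(1 - ln2/kappa)``.  Requires 0 < fwhm < 360.
    """
    f = np.asarray(fwhm_deg, dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 360.0):
        raise ValueError("FWHM must lie strictly between 0 and 360 degrees")
    return _LN2 / (1.0 - np.cos(np.deg2rad(f) / 2.0))


def fwhm_from_kappa(kappa):
    """Full width at half maximum (degrees) of the peak-normalized von Mises.

    For kappa < ln2/2 the curve never falls to half its baseline-subtracted
    peak, so the width is reported as 360 degrees.
    """
    k = np.asarray(kappa, dtype=float)
    out = np.full(k.shape, 360.0)
    ok = k >= _LN2 / 2.0
    out[ok] = 2.0 * np.rad2deg(np.arccos(1.0 - _LN2 / k[ok]))
    if np.ndim(kappa) == 0:
        return float(out)
    return out
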