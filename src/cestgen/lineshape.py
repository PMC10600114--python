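"""Absorption lineshapes for the semisolid magnetization-transfer pool.

A lineshape-approximated semisolid pool contributes a longitudinal
saturation rate ``W = pi * omega_1^2 * g(delta_omega)`` instead of explicit
transverse dynamics.  ``g`` is the absorption lineshape value in seconds at
the offset ``delta_omega`` (rad/s) from the pool's resonance.

The super-Lorentzian is the standard powder average over the fiber angle::

    g(D) = sqrt(2/pi) * T2s * int_0^{pi/2} sin(t) / |3 cos^2 t - 1|
           * exp(-2 (D * T2s / (3 cos^2 t - 1))^2) dt

It diverges on resonance; following common practice the inner band (by
default +-1 ppm around the semisolid resonance) is replaced by a smooth
polynomial interpolant through the quadrature samples at 1x, 1.5x and 2x
the band edge (even in the offset, exactly continuous at the edge).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .pools import LINESHAPE_LORENTZIAN, LINESHAPE_SUPER_LORENTZIAN

_QUAD_POINTS = 2000


def lorentzian_g(delta_omega, t2s):
    delta_omega = np.asarray(delta_omega, float)
    t2s = np.asarray(t2s, float)
    return (t2s / np.pi) / (1.0 + (delta_omega * t2s) ** 2)


@lru_cache(maxsize=8)
def _gauss_nodes(n):
    # Gauss-Legendre nodes/weights mapped to x = cos(theta) in [0, 1]
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def super_lorentzian_g(delta_omega, t2s, n_points: int = _QUAD_POINTS):
    """Super-Lorentzian absorption value by fixed-order quadrature.

    Broadcasts over ``delta_omega`` and ``t2s``.  No on-resonance handling:
    use :func:`lineshape_g` with ``interp_band_rad`` for offsets near the
    pool resonance.
    """
    delta_omega = np.asarray(delta_omega, float)
    t2s = np.asarray(t2s, float)
    if (t2s <= 0).any():
        raise ValueError("T2s must be positive")
    x, w = _gauss_nodes(n_points)
    u = 3.0 * x**2 - 1.0  # in [-1, 2]; integrable singularity at u = 0
    d = (delta_omega * t2s)[..., None]
    arg = 2.0 * (d / u) ** 2
    with np.errstate(over="ignore"):
        vals = np.exp(-np.minimum(arg, 745.0)) / np.abs(u)
    vals[arg >= 745.0] = 0.0
    integral = (vals * w).sum(axis=-1)
    return np.sqrt(2.0 / np.pi) * t2s * integral


def _band_fit(band_edges, t2s, n_points):
    """Batched smooth interpolant across the on-resonance band.

    The lineshape is even, so the band is bridged with the even polynomial
    ``c0 + c1 u + c2 u^2`` in ``u = (delta_omega / band)^2`` interpolating
    the quadrature samples at 1x, 1.5x and 2x the band edge exactly
    (continuous at the edge, zero slope on resonance).
    """
    factors = np.array([1.0, 1.5, 2.0])
    xs = band_edges[..., None] * factors  # (..., 3)
    ys = super_lorentzian_g(xs, t2s[..., None], n_points)
    u = factors**2
    v = u[:, None] ** np.arange(3)  # (3, 3) Vandermonde in u, shared
    coef = np.linalg.solve(
        np.broadcast_to(v, ys.shape[:-1] + (3, 3)), ys[..., None]
    )[..., 0]
    return coef


def lineshape_g(delta_omega, t2s, kind: str, interp_band_rad=None,
                n_points: int = _QUAD_POINTS):
    """Absorption lineshape value g (seconds).

    Parameters
    ----------
    delta_omega
        Offset of the saturation frequency from the pool resonance, rad/s.
    t2s
        Transverse relaxation time of the semisolid pool, s.
    kind
        ``"lorentzian"`` or ``"super-lorentzian"``.
    interp_band_rad
        Half-width (rad/s) of the on-resonance band inside which the
        super-Lorentzian is replaced by the cubic band fit.  ``None``
        disables interpolation (the raw quadrature is returned everywhere).
    """
    delta_omega = np.asarray(delta_omega, float)
    t2s = np.asarray(t2s, float)
    if (np.asarray(t2s) <= 0).any():
        raise ValueError("T2s must be positive")
    if kind == LINESHAPE_LORENTZIAN:
        return lorentzian_g(delta_omega, t2s)
    if kind != LINESHAPE_SUPER_LORENTZIAN:
        raise ValueError(f"unknown lineshape kind {kind!r}")
    g = super_lorentzian_g(delta_omega, t2s, n_points)
    if interp_band_rad is None:
        return g
    band = np.broadcast_to(np.asarray(interp_band_rad, float), g.shape)
    t2b = np.broadcast_to(t2s, g.shape)
    dw = np.broadcast_to(delta_omega, g.shape)
    inner = np.abs(dw) < band
    if inner.any():
        coef = _band_fit(band[inner], t2b[inner], n_points)  # (k, 3)
        u = ((dw[inner] / band[inner]) ** 2)[:, None] ** np.arange(3)
        g = np.array(g, copy=True)
        g[inner] = (coef * u).sum(axis=-1)
    return g
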