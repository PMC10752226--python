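"""Closed-form reference solutions used as independent numerical oracles.

These are textbook potential-theory results kept separate from the
production forward models: they serve to validate the boundary-element
solver on geometries where an analytic answer exists.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre

__all__ = ["dipole_potential_infinite", "dipole_in_insulated_sphere"]


def dipole_potential_infinite(obs, r0, p, sigma):
    """Potential of a current dipole in an unbounded homogeneous medium.

    phi(r) = p . (r - r0) / (4 pi sigma |r - r0|^3)
    """
    obs = np.atleast_2d(obs)
    d = obs - np.asarray(r0, dtype=float)
    r3 = np.linalg.norm(d, axis=1) ** 3
    return (d @ np.asarray(p, dtype=float)) / (4.0 * np.pi * sigma * r3)


def _monopole_series_surface(obs_unit, r0, radius, n_terms):
    """Sum_n (2n+1)/n * |r0|^n P_n(cos gamma) / R^(n+1), n >= 1.

    This is the surface potential (up to I/(4 pi sigma) and an additive
    constant) of a point current source at ``r0`` inside an insulated
    homogeneous sphere of the given radius.
    """
    b = np.linalg.norm(r0)
    if b == 0:
        cosg = np.zeros(len(obs_unit))
        b_hat = np.zeros(3)
    else:
        b_hat = r0 / b
        cosg = obs_unit @ b_hat
    out = np.zeros(len(obs_unit))
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / n * (b**n / radius ** (n + 1)) * eval_legendre(n, cosg)
    return out


def dipole_in_insulated_sphere(radius, sigma, r0, p, obs_points,
                               n_terms: int = 80, h: float = 1e-5):
    """Surface potential of a current dipole inside an insulated sphere.

    The classical Legendre-series solution for a point current source in a
    homogeneous conducting sphere (centred at the origin, radius ``radius``,
    conductivity ``sigma``, insulated exterior) is differentiated with
    respect to the source position (central differences, step ``h``) to
    obtain the dipole solution.  Observation points must lie on the sphere
    surface; the returned potentials have zero mean removed by the caller
    if a particular reference is required.

    Converges rapidly for source eccentricity |r0|/radius well below 1.
    """
    obs = np.atleast_2d(np.asarray(obs_points, dtype=float))
    obs_unit = obs / np.linalg.norm(obs, axis=1, keepdims=True)
    r0 = np.asarray(r0, dtype=float)
    p = np.asarray(p, dtype=float)
    phi = np.zeros(len(obs))
    for k in range(3):
        e = np.zeros(3)
        e[k] = h
        fp = _monopole_series_surface(obs_unit, r0 + e, radius, n_terms)
        fm = _monopole_series_surface(obs_unit, r0 - e, radius, n_terms)
        phi += p[k] * (fp - fm) / (2 * h)
    return phi / (4.0 * np.pi * sigma)
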