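"""Dimensionless temperature field of the uniform square sheet source.

The square occupies ``[-1/2, 1/2]^2`` at the interface plane ``z = 0`` in
coordinates reduced by the side length ``a``.  The field shape is the Newtonian
potential of a uniform unit-density sheet,

    I(xa, ya, za) = int_{-1/2}^{1/2} dxi int_{-1/2}^{1/2} deta
                    1 / sqrt((xa - xi)^2 + (ya - eta)^2 + za^2),

so the physical temperature increase is ``t1 * I``.  Two routes are provided:
an adaptive 2-D quadrature valid anywhere in space, and the exact closed form
on the surface ``za = 0`` obtained by integrating ``1/R`` over the square in
elementary functions.  The closed form is validated against the quadrature in
the test suite rather than trusted on faith.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

__all__ = [
    "ConvergenceError",
    "DegeneratePointError",
    "square_shape_quadrature",
    "square_shape_surface",
]

_HALF = 0.5
#: evaluation closer than this to a corner of the square is degenerate
CORNER_GUARD = 1e-12


class DegeneratePointError(ValueError):
    """Evaluation exactly at a square corner, where the closed form degenerates."""


class ConvergenceError(RuntimeError):
    """Adaptive quadrature failed to reach the requested tolerance."""

    def __init__(self, message: str, achieved_error: float):
        super().__init__(message)
        self.achieved_error = achieved_error


def square_shape_quadrature(
    xa: float, ya: float, za: float = 0.0, tol: float = 1e-9
) -> float:
    """Evaluate the square-sheet potential anywhere by adaptive 2-D quadrature.

    Parameters are the reduced coordinates ``x/a, y/a, z/a``.  The integrand
    has an integrable ``1/R`` singularity when the field point lies on the
    sheet; it is handled by splitting the integration domain at the field
    point so the singularity sits on panel corners.

    Returns the dimensionless field value (multiply by ``t1`` for deg C).

    Raises
    ------
    ConvergenceError
        If the error estimate exceeds ``tol`` relative after full refinement.
    """
    xa, ya, za = float(xa), float(ya), float(za)
    z2 = za * za

    def integrand(eta: float, xi: float) -> float:
        return 1.0 / np.sqrt((xa - xi) ** 2 + (ya - eta) ** 2 + z2)

    xi_breaks = [-_HALF, _HALF]
    eta_breaks = [-_HALF, _HALF]
    if za == 0.0:
        # split so the 1/R singular point becomes a panel corner
        if -_HALF < xa < _HALF:
            xi_breaks = [-_HALF, xa, _HALF]
        if -_HALF < ya < _HALF:
            eta_breaks = [-_HALF, ya, _HALF]

    total = 0.0
    err = 0.0
    for x0, x1 in zip(xi_breaks[:-1], xi_breaks[1:]):
        for y0, y1 in zip(eta_breaks[:-1], eta_breaks[1:]):
            v, e = integrate.dblquad(
                integrand, x0, x1, y0, y1, epsabs=tol, epsrel=tol
            )
            total += v
            err += e
    if err > max(tol * abs(total), 1e-14) * 10.0:
        raise ConvergenceError(
            f"quadrature error estimate {err:.3e} exceeds tolerance "
            f"{tol:.1e} at ({xa}, {ya}, {za})",
            achieved_error=err,
        )
    return total


def _term(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    # antiderivative of 1/sqrt(u^2+v^2): F = u asinh(v/|u|) + v asinh(u/|v|);
    # the limit of either summand as its prefactor -> 0 is 0
    out = np.zeros(np.broadcast(u, v).shape)
    au, av = np.abs(u), np.abs(v)
    nz_u = au > 0.0
    nz_v = av > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(nz_u, u * np.arcsinh(np.where(nz_u, v / np.where(nz_u, au, 1.0), 0.0)), 0.0)
        out = out + np.where(nz_v, v * np.arcsinh(np.where(nz_v, u / np.where(nz_v, av, 1.0), 0.0)), 0.0)
    return out


def _surface_limit(xa, ya):
    """Closed form without the corner guard; at exact corners the degenerate
    log term is replaced by its (zero) continuous limit, which is exact."""
    xa = np.asarray(xa, dtype=float)
    ya = np.asarray(ya, dtype=float)
    total = np.zeros(np.broadcast(xa, ya).shape)
    for i, xi in enumerate((-_HALF, _HALF)):
        for j, eta in enumerate((-_HALF, _HALF)):
            sign = 1.0 if (i + j) % 2 == 0 else -1.0
            total = total + sign * _term(xi - xa, eta - ya)
    return total


def square_shape_surface(xa, ya):
    """Exact closed form of the square-sheet potential on the surface ``za = 0``.

    Accepts scalars or broadcastable arrays.  Strictly positive, maximal at
    the origin, and equal to :func:`square_shape_quadrature` at ``za = 0``.

    Raises
    ------
    DegeneratePointError
        If any point coincides with a square corner ``(+-1/2, +-1/2)``, where
        the logarithmic antiderivative degenerates; offset the point by
        ~1e-12 instead.
    """
    xa = np.asarray(xa, dtype=float)
    ya = np.asarray(ya, dtype=float)
    at_corner = (np.abs(np.abs(xa) - _HALF) < CORNER_GUARD) & (
        np.abs(np.abs(ya) - _HALF) < CORNER_GUARD
    )
    if np.any(at_corner):
        raise DegeneratePointError(
            "evaluation at a square corner (+-1/2, +-1/2) is degenerate; "
            "offset the point by ~1e-12"
        )
    total = _surface_limit(xa, ya)
    if total.ndim == 0:
        return float(total)
    return total
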