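"""Dimensionless temperature field of the circular wire (O-ring) source.

The ring has diameter ``a`` (radius 1/2 in reduced units) and sits at height
``z0`` above the interface.  The field shape is

    J(ra, za, z0a) = int_0^pi dphi /
        sqrt(1 + (2 ra)^2 - 4 ra cos(phi) + 4 (za - z0a)^2)

in coordinates reduced by ``a``; the physical increase is ``t2 * J``.  On the
ring plane the integral reduces exactly to a complete elliptic integral of
the first kind:

    J(ra, z0a, z0a) = (2 / (1 + u)) * K(2 sqrt(u) / (1 + u)),  u = 2 ra,

with the modulus convention K(k) = int_0^{pi/2} dtheta / sqrt(1 - k^2 sin^2).
The field diverges logarithmically on the wire itself (ra = 1/2 at the ring
height), as an ideal line source must.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.special import ellipkm1

__all__ = [
    "SingularPointError",
    "OutOfValidityError",
    "ring_shape_integral",
    "ring_shape_surface",
    "ring_shape_exact",
    "WIRE_GUARD",
]

#: points within this distance of the wire (in both ra and za-z0a) are singular
WIRE_GUARD = 1e-6

#: default reduced standoff z0/a used when only a surface map is requested
DEFAULT_Z0A = 0.02


class SingularPointError(ValueError):
    """Evaluation on (or within the guard band of) the ring wire itself."""


class OutOfValidityError(ValueError):
    """Surface closed form requested outside its validity range ra < 1/2."""


def ring_shape_integral(
    ra: float, za: float = 0.0, z0a: float = 0.0, tol: float = 1e-10
) -> float:
    """Angular integral of the ring source at reduced radius ``ra``, height ``za``.

    ``z0a`` is the reduced ring standoff; only ``|za - z0a|`` enters.  Returns
    the dimensionless field value (multiply by ``t2`` for deg C).

    Raises
    ------
    SingularPointError
        If the point lies on the wire: ``|ra - 1/2| < 1e-6`` and
        ``|za - z0a| < 1e-6`` simultaneously.
    """
    ra = float(ra)
    if ra < 0.0:
        raise ValueError(f"ra must be >= 0, got {ra}")
    dz = float(za) - float(z0a)
    if abs(ra - 0.5) < WIRE_GUARD and abs(dz) < WIRE_GUARD:
        raise SingularPointError(
            f"point (ra={ra}, za-z0a={dz}) lies on the ring wire; "
            "the ideal line source diverges there"
        )
    b = 1.0 + (2.0 * ra) ** 2 + 4.0 * dz * dz
    c = 4.0 * ra

    def integrand(phi: float) -> float:
        return 1.0 / math.sqrt(b - c * math.cos(phi))

    # integrand is smooth (b > c away from the wire); near-wire points get a
    # breakpoint at phi=0 where the near-singular peak sits
    val, _ = integrate.quad(
        integrand, 0.0, math.pi, epsabs=tol, epsrel=tol, limit=200
    )
    return val


def ring_shape_exact(ra, za=0.0, z0a=0.0):
    """Exact elliptic-integral evaluation of the ring integral anywhere off-wire.

    The angular integral equals ``(2/sqrt(b+c)) K(k)`` with ``k^2 = 2c/(b+c)``,
    ``b = 1 + (2 ra)^2 + 4 (za-z0a)^2`` and ``c = 4 ra``; this is the same
    quantity :func:`ring_shape_integral` computes numerically, vectorized for
    grid evaluation.

    Raises
    ------
    SingularPointError
        If any point lies within the wire guard band.
    """
    ra = np.asarray(ra, dtype=float)
    dz = np.asarray(za, dtype=float) - np.asarray(z0a, dtype=float)
    if np.any(ra < 0.0):
        raise ValueError("ra must be >= 0")
    on_wire = (np.abs(ra - 0.5) < WIRE_GUARD) & (np.abs(dz) < WIRE_GUARD)
    if np.any(on_wire):
        raise SingularPointError("grid contains points on the ring wire")
    b = 1.0 + (2.0 * ra) ** 2 + 4.0 * dz * dz
    c = 4.0 * ra
    # 1 - m = (b - c)/(b + c), accurate near the wire where m -> 1
    one_minus_m = (b - c) / (b + c)
    out = 2.0 / np.sqrt(b + c) * ellipkm1(one_minus_m)
    if out.ndim == 0:
        return float(out)
    return out


def _surface_scalar(ra: float) -> float:
    u = 2.0 * ra
    # K(k) with k = 2 sqrt(u)/(1+u); m = k^2, 1 - m = ((1-u)/(1+u))^2.
    # ellipkm1 takes 1 - m directly, which stays accurate as u -> 1.
    one_minus_m = ((1.0 - u) / (1.0 + u)) ** 2
    return 2.0 / (1.0 + u) * ellipkm1(one_minus_m)


def ring_shape_surface(ra):
    """Elliptic-integral closed form of the ring field on its own plane.

    Valid for ``0 <= ra < 1/2`` (inside the ring, away from the wire); equals
    :func:`ring_shape_integral` with ``za = z0a``.  At ``ra = 0`` the value is
    exactly pi; it increases monotonically and diverges like ``-ln(1/2 - ra)``
    as ``ra -> 1/2``.

    Accepts scalars or arrays.

    Raises
    ------
    OutOfValidityError
        If any ``ra >= 1/2``; use :func:`ring_shape_integral` with an explicit
        standoff ``z0a`` there.
    """
    arr = np.asarray(ra, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("ra must be >= 0")
    if np.any(arr >= 0.5):
        raise OutOfValidityError(
            "surface closed form is valid only for ra < 1/2; evaluate "
            "ring_shape_integral(ra, za=0, z0a=...) with an explicit standoff "
            "at or beyond the wire"
        )
    if arr.ndim == 0:
        return _surface_scalar(float(arr))
    return np.vectorize(_surface_scalar)(arr)
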