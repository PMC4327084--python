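"""Heater and media parameter types plus the derived power/temperature scales.

All inputs are SI.  Temperatures are handled as increments above the ambient
baseline ``T0``; the physics never depends on ``T0`` itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


class ValidationError(ValueError):
    """A physical parameter violates its domain (e.g. non-positive length)."""


class ThinLayerWarning(UserWarning):
    """A geometric ratio leaves the thin-layer / small-standoff regime."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise ValidationError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class Media:
    """Thermal conductivities of the two half-spaces, W/(m K).

    ``kappa_e`` is the upper medium (air), ``kappa_i`` the lower (tissue).
    Only the sum enters the field solution.
    """

    kappa_e: float
    kappa_i: float

    def __post_init__(self) -> None:
        _require_positive("kappa_e", self.kappa_e)
        _require_positive("kappa_i", self.kappa_i)

    @property
    def kappa_sum(self) -> float:
        return self.kappa_e + self.kappa_i


@dataclass(frozen=True)
class SquareHeater:
    """Square resistive-sheet heater driven by lateral electrodes.

    Parameters
    ----------
    a : side length, m
    d : conductive-layer thickness, m
    rho : specific resistance of the layer material, Ohm m
    U : voltage between the lateral electrodes, V
    """

    a: float
    d: float
    rho: float
    U: float

    def __post_init__(self) -> None:
        _require_positive("a", self.a)
        _require_positive("d", self.d)
        _require_positive("rho", self.rho)
        _require_positive("U", self.U)
        if self.d / self.a >= 0.1:
            warnings.warn(
                f"d/a = {self.d / self.a:.3g} >= 0.1: thin-layer assumption "
                "is questionable",
                ThinLayerWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class RingHeater:
    """O-ring wire heater of diameter ``a`` placed at height ``z0``.

    Parameters
    ----------
    a : ring diameter (equal to the square side), m
    z0 : standoff of the ring plane above the interface, m
    S : conductor cross-section area, m^2
    R_total : total ring resistance, Ohm
    U : voltage across the ring, V
    """

    a: float
    z0: float
    S: float
    R_total: float
    U: float

    def __post_init__(self) -> None:
        _require_positive("a", self.a)
        _require_positive("z0", self.z0)
        _require_positive("S", self.S)
        _require_positive("R_total", self.R_total)
        _require_positive("U", self.U)
        if self.z0 / self.a >= 0.1:
            warnings.warn(
                f"z0/a = {self.z0 / self.a:.3g} >= 0.1: small-standoff "
                "assumption is questionable",
                ThinLayerWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ThermalScales:
    """Baseline temperature and the two characteristic scale increments.

    ``t1`` multiplies the dimensionless square-source shape, ``t2`` the ring
    shape; both in degrees Celsius (equivalently kelvin increments).
    """

    T0: float = 0.0
    t1: float = 0.0
    t2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t1", "t2"):
            v = getattr(self, name)
            if v < 0.0 or not math.isfinite(v):
                raise ValidationError(f"{name} must be >= 0 and finite, got {v!r}")
        if not math.isfinite(self.T0):
            raise ValidationError(f"T0 must be finite, got {self.T0!r}")

    @classmethod
    def from_heaters(
        cls,
        media: Media,
        square: SquareHeater | None = None,
        ring: RingHeater | None = None,
        T0: float = 0.0,
    ) -> "ThermalScales":
        """Derive (t1, t2) from electrical/geometric heater parameters."""
        t1 = thermal_scale_t1(square, media) if square is not None else 0.0
        t2 = thermal_scale_t2(ring, media) if ring is not None else 0.0
        return cls(T0=T0, t1=t1, t2=t2)


def current_density(square: SquareHeater) -> float:
    """Current density in the sheet, A/m^2, directed along x: U/(a rho)."""
    return square.U / (square.a * square.rho)


def square_power_density(square: SquareHeater) -> float:
    """Volumetric Joule heat density of the sheet, W/m^3: U^2/(a^2 rho)."""
    return square.U**2 / (square.a**2 * square.rho)


def ring_power_density(ring: RingHeater) -> float:
    """Volumetric Joule heat density of the ring conductor, W/m^3.

    Q2 = U^2 / (pi R a S); Q2*S is the power per unit ring length, and
    Q2*S*pi*a recovers the total dissipated power U^2/R.
    """
    return ring.U**2 / (math.pi * ring.R_total * ring.a * ring.S)


def thermal_scale_t1(square: SquareHeater, media: Media) -> float:
    """Square-source scale temperature: Q1*d*a / (2 pi (kappa_e + kappa_i))."""
    q1 = square_power_density(square)
    return q1 * square.d * square.a / (2.0 * math.pi * media.kappa_sum)


def thermal_scale_t2(ring: RingHeater, media: Media) -> float:
    """Ring-source scale temperature: Q2*S / (pi (kappa_e + kappa_i))."""
    q2 = ring_power_density(ring)
    return q2 * ring.S / (math.pi * media.kappa_sum)
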