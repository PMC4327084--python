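"""Independent brute-force oracles used to validate the analytic kernels.

These deliberately avoid the code paths under test: the square oracle is a
Richardson-extrapolated midpoint-rule sum; the ring oracle is a dense
trapezoid rule.  Both are slow and dumb on purpose.
"""

import numpy as np


def midpoint_square(x: float, y: float, z: float = 0.0, n: int = 1000) -> float:
    """Midpoint-rule sum of 1/R over the unit square [-1/2, 1/2]^2.

    ``n`` must be even so no sample coincides with an on-sheet field point at
    a midpoint node.
    """
    assert n % 2 == 0
    h = 1.0 / n
    c = np.linspace(-0.5 + h / 2, 0.5 - h / 2, n)
    xi, eta = np.meshgrid(c, c)
    r = np.sqrt((x - xi) ** 2 + (y - eta) ** 2 + z * z)
    return float(np.sum(1.0 / r) * h * h)


def square_oracle(x: float, y: float, z: float = 0.0, n: int = 1000) -> float:
    """Richardson extrapolation of the midpoint sum (leading error ~ h)."""
    v1 = midpoint_square(x, y, z, n)
    v2 = midpoint_square(x, y, z, 2 * n)
    return 2.0 * v2 - v1


def ring_oracle(ra: float, dz: float = 0.0, n: int = 10**6) -> float:
    """Dense trapezoid rule for the ring angular integral."""
    phi = np.linspace(0.0, np.pi, n)
    f = 1.0 / np.sqrt(1.0 + (2.0 * ra) ** 2 - 4.0 * ra * np.cos(phi) + 4.0 * dz * dz)
    return float(np.trapezoid(f, phi))
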