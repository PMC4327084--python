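# planarheat

Steady-state thermal field of a combined plane heater — a square resistive
sheet plus a supplemental O-ring wire — at the interface of two semi-infinite
media (air above, biological tissue below). The package evaluates the two
dimensionless source kernels, superposes them into surface temperature maps,
extracts isotherms, quantifies the flatness of the central heating zone
intended for a multichannel transcutaneous oxygen-sensor matrix, and finds
the ring/square power balance that maximizes that flatness.

## Physics summary

Both heaters inject heat at (or just above, for the ring) the plane `z = 0`
separating media with conductivities `kappa_e` (air) and `kappa_i` (tissue).
In coordinates reduced by the square side `a`, the surface temperature
increase is

    dT(x, y) = t1 * I_square(x, y) + t2 * J_ring(r; z0/a),   r = hypot(x, y)

* `I_square` is the Newtonian potential of a uniform unit sheet over
  `[-1/2, 1/2]^2` — evaluated either by adaptive 2-D quadrature (valid
  anywhere in space) or by its exact elementary closed form on the surface.
  Its center value is `4 ln(1 + sqrt 2) ≈ 3.5255`.
* `J_ring` is the angular integral of an ideal circular line source of
  diameter `a` at reduced standoff `z0/a`; on the ring plane it reduces
  exactly to `(2/(1+u)) K(2 sqrt(u)/(1+u))` with `u = 2r/a` (complete
  elliptic integral of the first kind), equal to `pi` at the center and
  logarithmically divergent on the wire.
* The scale temperatures derive from the electrical parameters:
  `t1 = Q1 d a / (2 pi (kappa_e + kappa_i))` with `Q1 = U1^2/(a^2 rho)`, and
  `t2 = Q2 S / (pi (kappa_e + kappa_i))` with `Q2 = U2^2/(pi R a S)` — or can
  be supplied directly.

The square source is hottest at the center; the ring is coolest there.
Superposing them with the right ratio `t2/t1` flattens the central zone —
`flatten_ratio` minimizes the worst-case deviation from the center value over
a probe disc.

## CLI

```bash
# full simulation: grid CSVs, isotherm CSV, homogeneity JSON, run log
planarheat simulate --config examples/fig5.json --out out/

# per-source axis profile table (dT1, dT2, total vs x)
planarheat profile --config examples/fig5.json --out profile.csv

# optimal ring/square balance for a flat central zone
planarheat design --z0a 0.02 --probe-radius 0.2

# seeded randomized parameter sets for testing
planarheat fixtures --seed 7 --n 10
```

Configs are flat JSON (see `examples/`): either direct `scales`
(`{T0, t1, t2}`) or electrical blocks (`kappa_e`, `kappa_i`, `square`,
`ring`), plus an optional `sim` block (`grid_n`, `extent`, `z0a`,
`probe_radius`, `epsilon`, `levels`). Any key can be overridden on the
command line with its dotted name, e.g. `--scales.t2 0.4`; the flag wins.
`examples/electrical.json` documents the bundled default conductivities
(`kappa_e = 0.026`, `kappa_i = 0.5` W/(m K)) — implementation defaults, not
physical constants of the model.

## API sketch

```python
import numpy as np
from planarheat import (
    ThermalScales, total_surface_field, homogeneity_report, flatten_ratio,
)

scales = ThermalScales(T0=39.1, t1=0.65, t2=0.5)
grid = total_surface_field(scales, z0a=0.02)           # 201x201 over [-1,1]^2
report = homogeneity_report(grid, probe_radius=0.2, epsilon=0.1)
best = flatten_ratio(z0a=0.02, probe_radius=0.2)       # optimal t2/t1
```

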