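{
  "kappa_e": 0.026,
  "kappa_i": 0.5,
  "T0": 39.1,
  "square": {"a": 0.012, "d": 5e-05, "rho": 2e-06, "U": 0.35},
  "ring": {"a": 0.012, "z0": 0.00024, "S": 5e-09, "R": 4.0, "U": 1.2},
  "sim": {"grid_n": 101, "extent": 1.0}
}
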