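{
  "scales": {"T0": 39.1, "t1": 0.65, "t2": 0.5},
  "sim": {
    "grid_n": 201,
    "extent": 1.0,
    "z0a": 0.02,
    "probe_radius": 0.2,
    "epsilon": 0.1,
    "levels": []
  }
}
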