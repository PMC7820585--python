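{
  "r": 0.1,
  "x": 1.0,
  "omega": 5.0,
  "alpha": 1.2,
  "beta": 5.0,
  "pi": 10.0,
  "gamma": 0.3333333333333333,
  "T": 50,
  "N": 500,
  "n": 5,
  "K": 50,
  "threshold": 0.0,
  "s_min": -50.0,
  "s_max": 50.0,
  "s_steps": 1001,
  "p_steps": 101,
  "mu": 5.5,
  "sigma": 4.0,
  "perturbation_variant": "variance_preserving"
}
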