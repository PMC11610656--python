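{
  "r": {"kind": "normal", "a": 2.5, "b": 1.5},
  "K": {"kind": "normal", "a": 10000.0, "b": 5000.0},
  "kappa_D": {"kind": "normal", "a": 2.0, "b": 1.0, "zero_inflation_prob": 0.1},
  "alpha_A": {"kind": "lognormal", "a": -3.7, "b": 1.0},
  "kappa_S": {"kind": "lognormal", "a": -0.2, "b": 1.0, "zero_inflation_prob": 0.1},
  "delta_A": {"kind": "loguniform", "a": 0.018, "b": 5.0},
  "delta_D": {"kind": "loguniform", "a": 0.001, "b": 1.0},
  "eps_D": {"kind": "uniform", "a": 0.0, "b": 1.0},
  "eps_U": {"kind": "loguniform", "a": 1e-05, "b": 0.1},
  "alpha_D": {"kind": "lognormal", "a": -2.7, "b": 1.0},
  "alpha_U": {"kind": "uniform", "a": 0.0, "b": 10.0},
  "gamma_U": {"kind": "loguniform", "a": 0.01, "b": 1000.0},
  "kappa_A": {"kind": "lognormal", "a": -8.0, "b": 1.0, "zero_inflation_prob": 0.1},
  "delta_U": {"kind": "lognormal", "a": -8.0, "b": 4.0},
  "beta": {"kind": "loguniform", "a": 0.01, "b": 100.0, "zero_inflation_prob": 0.1},
  "eps_S": {"kind": "loguniform", "a": 1e-05, "b": 0.1},
  "delta_S": {"kind": "loguniform", "a": 1e-09, "b": 0.01}
}
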