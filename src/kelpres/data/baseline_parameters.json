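{
  "r": 2.5,
  "K": 10000.0,
  "kappa_D": 1.95,
  "alpha_A": 0.025,
  "kappa_S": 0.81,
  "delta_A": 1.8,
  "delta_D": 0.3,
  "eps_D": 0.7,
  "eps_U": 0.1,
  "alpha_D": 0.062,
  "alpha_U": 4.77,
  "gamma_U": 3.42,
  "kappa_A": 0.00013,
  "delta_U": 0.0004,
  "beta": 0.1,
  "eps_S": 0.1,
  "delta_S": 0.0001
}
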