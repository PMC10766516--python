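{
  "comment": "Working-variable and gradient-correction constants of the parent nonseparable functional family, transcribed from the published parameterization; gamma_x enters u_x(s) = gamma_x s^2/(1+gamma_x s^2), omega_x enters v_x(rho) = omega_x rho^(1/3)/(1+omega_x rho^(1/3)).",
  "gamma_x": 0.004,
  "omega_x": 2.5,
  "correlation": "pw92",
  "pbe_beta": 0.066725,
  "pbe_gamma": 0.031090690869654894
}
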