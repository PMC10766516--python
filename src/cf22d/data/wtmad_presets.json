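{
  "gmtkn55": {
    "comment": "Literature constants of the GMTKN55 weighting scheme: overall mean absolute reference energy (kcal/mol) and the WTMAD-1 magnitude bins [lo, hi, weight] in kcal/mol (hi = null means unbounded).",
    "overall_mean_abs": 56.84,
    "bins": [
      [0.0, 7.5, 10.0],
      [7.5, 75.0, 1.0],
      [75.0, null, 0.1]
    ]
  }
}
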