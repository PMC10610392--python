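{
  "intercept": 0.408,
  "coefficients": {"DH": -1.599, "TKW": 0.593, "CT": 0.795, "Pn": 0.626},
  "partial_r2": {"Pn": 0.545, "CT": 0.190, "TKW": 0.089, "DH": 0.043},
  "total_r2": 0.868,
  "residual": 0.364,
  "average_accuracy": 96.745
}
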