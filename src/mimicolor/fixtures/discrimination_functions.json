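{
  "successive_blue": {
    "form": "logistic3",
    "coefficients": {"K": 0.990, "r": 53.8, "Mo": 0.528},
    "ci95": {"K": [0.969, 1.01], "r": [45.3, 66.3], "Mo": [0.474, 0.571]},
    "clamp_floor": 0.5
  },
  "successive_yellow": {
    "form": "logistic3",
    "coefficients": {"K": 0.951, "r": 47.2, "Mo": 0.555},
    "ci95": {"K": [0.913, 0.989], "r": [35.7, 69.5], "Mo": [0.420, 0.651]},
    "clamp_floor": 0.5
  },
  "absolute": {
    "form": "logistic4",
    "coefficients": {"K": 0.842, "Mo": 0.441, "xmid": 0.081, "scal": 0.009},
    "ci95": {"K": [0.766, 0.919], "Mo": [0.377, 0.505], "xmid": [0.076, 0.086], "scal": [0.004, 0.015]},
    "clamp_floor": 0.5
  }
}
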