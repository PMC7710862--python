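{
  "wc_petal": {
    "description": "Wahlenbergia cuspidata adaxial petal colour loci (x'y' frame)",
    "margin_x": {"family": "gamma", "params": [491.0, 659.0], "se": [136.0, 183.0]},
    "margin_y": {"family": "gamma", "params": [1270.0, 1150.0], "se": [353.0, 320.0]},
    "copula": {"family": "tawn2", "rotation": 270, "par1": -9.13, "par2": 0.244, "se": [4.75, 0.030]}
  },
  "wc_pollen": {
    "description": "Wahlenbergia cuspidata pollen-presenter colour loci (x'y' frame)",
    "margin_x": {"family": "gamma", "params": [182.0, 159.0], "se": [54.9, 48.0]},
    "margin_y": {"family": "weibull", "params": [22.8, 1.26], "se": [3.86, 0.012]},
    "copula": {"family": "tawn2", "rotation": 180, "par1": 3.61, "par2": 0.490, "se": [0.846, 0.110]}
  },
  "ez_lateral_petal": {
    "description": "Eulophia zeyheriana lateral-petal colour loci (x'y' frame)",
    "margin_x": {"family": "normal", "params": [0.761, 0.027], "se": [0.006, 0.004]},
    "margin_y": {"family": "normal", "params": [1.08, 0.012], "se": [0.002, 0.002]},
    "copula": {"family": "joe", "rotation": 90, "par1": -2.15, "par2": null, "se": [0.552]}
  },
  "ez_labellum": {
    "description": "Eulophia zeyheriana labellum colour loci (x'y' frame)",
    "margin_x": {"family": "normal", "params": [1.22, 0.070], "se": [0.015, 0.011]},
    "margin_y": {"family": "gamma", "params": [1370.0, 1100.0], "se": [423.0, 339.0]},
    "copula": {"family": "gumbel", "rotation": 180, "par1": 4.19, "par2": null, "se": [0.764]}
  }
}
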