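{
  "reference": "Value functions and weights transcribed from Gupta, M.; Lee, H. J.; Barden, C. J.; Weaver, D. F. The Blood-Brain Barrier (BBB) Score. J. Med. Chem. 2019, 62, 9824-9836.",
  "weights": {"aro": 1.0, "ha": 1.0, "mwhbn": 1.5, "tpsa": 2.0, "pka": 0.5},
  "aro_step": {"0": 0.336376, "1": 0.816016, "2": 1.0, "3": 0.691115, "4": 0.199399},
  "ha": {
    "domain": [5.0, 45.0],
    "coefficients": [4.43e-05, -0.004556, 0.12775, -0.463],
    "normalizer": 0.624231
  },
  "mwhbn": {
    "domain": [0.05, 0.45],
    "coefficients": [26.733, -31.495, 9.5202, -0.1358],
    "normalizer": 0.72258
  },
  "tpsa": {
    "domain": [0.0, 120.0],
    "coefficients": [-0.0067, 0.9598],
    "normalizer": 0.9598
  },
  "pka": {
    "domain": [3.0, 11.0],
    "coefficients": [0.00045068, -0.016331, 0.18618, -0.71043, 0.8579],
    "normalizer": 0.597488
  }
}
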