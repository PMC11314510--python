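{
  "MAM1": {
    "model_id": "MAM1",
    "intercept": -0.79,
    "coefficients": {
      "Plant sex": 0.54,
      "Sporophyte presence": -1.18,
      "Substrate breadth": -0.83
    },
    "scaling": {
      "Substrate breadth": [1.69, 0.94]
    },
    "cutoff": 0.21
  },
  "MAM2": {
    "model_id": "MAM2",
    "intercept": -1.65,
    "coefficients": {
      "Seta length": -0.61,
      "Substrate breadth": -0.9
    },
    "scaling": {
      "Seta length": [14.0, 13.32],
      "Substrate breadth": [1.8, 0.98]
    },
    "cutoff": 0.18
  }
}
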