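{
  "comment": "Identity-range presets for the four default properties. Weight order: hydrophobicity, size, coil propensity, thiol group. alpha/beta are gap initiation/extension penalties in normalized distance units. Ranges are half-open [low, high); the last range includes 100. The 30-40% row is the default preset.",
  "presets": [
    {"label": "0-10%",     "identity_low": 0,  "identity_high": 10,  "weights": [0.7, 0.15, 0.1, 0.05],  "alpha": 0.8, "beta": 0.2, "n_pairs": 1282},
    {"label": "10-20%",    "identity_low": 10, "identity_high": 20,  "weights": [0.3, 0.2, 0.15, 0.35],  "alpha": 0.6, "beta": 0.1, "n_pairs": 2023},
    {"label": "20-30%",    "identity_low": 20, "identity_high": 30,  "weights": [0.3, 0.2, 0.15, 0.35],  "alpha": 0.7, "beta": 0.1, "n_pairs": 1674},
    {"label": "30-40%",    "identity_low": 30, "identity_high": 40,  "weights": [0.25, 0.2, 0.15, 0.4],  "alpha": 0.7, "beta": 0.1, "n_pairs": 1100},
    {"label": "above-40%", "identity_low": 40, "identity_high": 100, "weights": [0.2, 0.2, 0.25, 0.35],  "alpha": 0.6, "beta": 0.1, "n_pairs": 705}
  ]
}
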