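{
  "description": "Reference cohort statistics (median organ dose, % of prescription) that the analytics pipeline must reproduce from the per-subject values to one decimal.",
  "summary": {
    "SOC": {
      "bowel": {"mean": 17.2, "sd": 9.8},
      "heart": {"mean": 12.6, "sd": 6.9},
      "kidneys": {"mean": 1.6, "sd": 0.5},
      "lungs": {"mean": 4.2, "sd": 0.8},
      "liver": {"mean": 2.3, "sd": 0.7}
    },
    "3D": {
      "bowel": {"mean": 31.7, "sd": 7.7},
      "heart": {"mean": 10.0, "sd": 1.1},
      "kidneys": {"mean": 81.6, "sd": 8.8},
      "lungs": {"mean": 52.6, "sd": 6.5},
      "liver": {"mean": 17.7, "sd": 5.9}
    }
  },
  "paired_reduction": {"lungs": 48.4},
  "reduction_vs_prescription": {
    "lungs": 95.8,
    "kidneys": 98.4,
    "liver": 97.7,
    "bowel": 82.8,
    "heart": 87.4
  }
}
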