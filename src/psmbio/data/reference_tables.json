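{
  "description": "Published reference values for the 224-patient contrast-MRI cirrhosis cohort: population descriptives, biomarker group comparisons, and biomarker correlations. Used by the reproduce command to check a recomputed analysis cell-by-cell.",
  "table1": {
    "n": 224,
    "continuous": {
      "age": {"mean": 60, "sd": 10},
      "bmi": {"mean": 31, "sd": 7.3},
      "meld": {"mean": 10.9, "sd": 5.3},
      "albumin": {"mean": 3.55, "sd": 0.65},
      "creatinine": {"mean": 0.93, "sd": 0.38},
      "tbili": {"mean": 1.64, "sd": 2.11},
      "inr": {"mean": 1.25, "sd": 0.35}
    },
    "counts": {
      "sex_m": 135,
      "sex_f": 89,
      "tips": 15,
      "sbp": 18,
      "varices_no": 60,
      "varices_small": 128,
      "varices_moderate": 18,
      "varices_large": 18,
      "vbh": 38,
      "thyroid": 19,
      "diabetes": 103,
      "ascites_no": 141,
      "ascites_trace": 32,
      "ascites_small": 23,
      "ascites_moderate": 19,
      "ascites_large": 9,
      "ph": 47
    },
    "etiology": {
      "viral": 69, "nash": 66, "etoh": 61, "other": 11,
      "etoh+viral": 11, "etoh+nash": 3, "nash+viral": 2, "viral+other": 1
    }
  },
  "table2": {
    "sex": {
      "groups": ["M", "F"],
      "sff": {"mean_a": 0.12, "sd_a": 0.08, "mean_b": 0.14, "sd_b": 0.07, "p": "0.004"},
      "smi": {"mean_a": 5.58, "sd_a": 2.11, "mean_b": 4.75, "sd_b": 1.61, "p": "<0.001"},
      "cefr_art": {"mean_a": 0.09, "sd_a": 0.13, "mean_b": 0.12, "sd_b": 0.11, "p": "0.11"},
      "cefr_pv": {"mean_a": 0.21, "sd_a": 0.15, "mean_b": 0.24, "sd_b": 0.13, "p": "0.12"},
      "cefr_del": {"mean_a": 0.24, "sd_a": 0.18, "mean_b": 0.27, "sd_b": 0.13, "p": "0.1"}
    },
    "api": {
      "groups": ["yes", "no"],
      "sff": {"mean_a": 0.12, "sd_a": 0.07, "mean_b": 0.13, "sd_b": 0.08, "p": "0.06"},
      "smi": {"mean_a": 4.68, "sd_a": 1.49, "mean_b": 5.59, "sd_b": 2.13, "p": "<0.001"},
      "cefr_art": {"mean_a": 0.09, "sd_a": 0.12, "mean_b": 0.11, "sd_b": 0.12, "p": "0.17"},
      "cefr_pv": {"mean_a": 0.2, "sd_a": 0.15, "mean_b": 0.23, "sd_b": 0.14, "p": "0.14"},
      "cefr_del": {"mean_a": 0.24, "sd_a": 0.2, "mean_b": 0.26, "sd_b": 0.14, "p": "0.59"}
    },
    "ph": {
      "groups": ["yes", "no"],
      "sff": {"mean_a": 0.11, "sd_a": 0.07, "mean_b": 0.13, "sd_b": 0.08, "p": "0.18"},
      "smi": {"mean_a": 4.37, "sd_a": 1.62, "mean_b": 5.48, "sd_b": 1.99, "p": "<0.001"},
      "cefr_art": {"mean_a": 0.07, "sd_a": 0.09, "mean_b": 0.11, "sd_b": 0.13, "p": "0.01"},
      "cefr_pv": {"mean_a": 0.18, "sd_a": 0.11, "mean_b": 0.23, "sd_b": 0.15, "p": "0.01"},
      "cefr_del": {"mean_a": 0.23, "sd_a": 0.2, "mean_b": 0.26, "sd_b": 0.15, "p": "0.31"}
    },
    "vpi": {
      "groups": ["yes", "no"],
      "sff": {"mean_a": 0.12, "sd_a": 0.07, "mean_b": 0.14, "sd_b": 0.08, "p": "0.06"},
      "smi": {"mean_a": 5.2, "sd_a": 1.77, "mean_b": 5.39, "sd_b": 2.41, "p": "0.57"},
      "cefr_art": {"mean_a": 0.09, "sd_a": 0.12, "mean_b": 0.13, "sd_b": 0.12, "p": "0.03"},
      "cefr_pv": {"mean_a": 0.21, "sd_a": 0.15, "mean_b": 0.25, "sd_b": 0.14, "p": "0.08"},
      "cefr_del": {"mean_a": 0.24, "sd_a": 0.17, "mean_b": 0.27, "sd_b": 0.12, "p": "0.19"}
    },
    "vbh": {
      "groups": ["yes", "no"],
      "sff": {"mean_a": 0.1, "sd_a": 0.06, "mean_b": 0.13, "sd_b": 0.08, "p": "0.01"},
      "smi": {"mean_a": 4.78, "sd_a": 1.35, "mean_b": 5.35, "sd_b": 2.06, "p": "0.04"},
      "cefr_art": {"mean_a": 0.1, "sd_a": 0.15, "mean_b": 0.1, "sd_b": 0.13, "p": "0.79"},
      "cefr_pv": {"mean_a": 0.22, "sd_a": 0.18, "mean_b": 0.22, "sd_b": 0.14, "p": "0.98"},
      "cefr_del": {"mean_a": 0.27, "sd_a": 0.25, "mean_b": 0.24, "sd_b": 0.17, "p": "0.45"}
    },
    "high_meld": {
      "groups": [">17", "<=17"],
      "sff": {"mean_a": 0.12, "sd_a": 0.08, "mean_b": 0.13, "sd_b": 0.08, "p": "0.59"},
      "smi": {"mean_a": 5.14, "sd_a": 2.29, "mean_b": 5.27, "sd_b": 1.92, "p": "0.79"},
      "cefr_art": {"mean_a": 0.06, "sd_a": 0.08, "mean_b": 0.11, "sd_b": 0.13, "p": "0.01"},
      "cefr_pv": {"mean_a": 0.16, "sd_a": 0.13, "mean_b": 0.23, "sd_b": 0.14, "p": "0.02"},
      "cefr_del": {"mean_a": 0.19, "sd_a": 0.18, "mean_b": 0.26, "sd_b": 0.15, "p": "0.05"}
    }
  },
  "table3": {
    "albumin": {
      "sff": {"r": -0.03, "ci": [-0.16, 0.1], "p": "0.63"},
      "smi": {"r": 0.1, "ci": [-0.03, 0.23], "p": "0.12"},
      "cefr_art": {"r": 0.06, "ci": [-0.07, 0.19], "p": "0.38"},
      "cefr_pv": {"r": 0.15, "ci": [0.02, 0.27], "p": "0.03"},
      "cefr_del": {"r": 0.13, "ci": [0.0, 0.26], "p": "0.05"}
    },
    "creatinine": {
      "sff": {"r": -0.05, "ci": [-0.18, 0.08], "p": "0.45"},
      "smi": {"r": 0.08, "ci": [-0.05, 0.21], "p": "0.21"},
      "cefr_art": {"r": -0.06, "ci": [-0.19, 0.07], "p": "0.36"},
      "cefr_pv": {"r": -0.04, "ci": [-0.17, 0.1], "p": "0.59"},
      "cefr_del": {"r": -0.04, "ci": [-0.17, 0.1], "p": "0.6"}
    },
    "tbili": {
      "sff": {"r": -0.12, "ci": [-0.25, 0.01], "p": "0.07"},
      "smi": {"r": -0.15, "ci": [-0.28, -0.02], "p": "0.02"},
      "cefr_art": {"r": -0.12, "ci": [-0.25, 0.01], "p": "0.06"},
      "cefr_pv": {"r": -0.22, "ci": [-0.35, -0.1], "p": "0.001"},
      "cefr_del": {"r": -0.2, "ci": [-0.32, -0.07], "p": "0.002"}
    },
    "inr": {
      "sff": {"r": -0.02, "ci": [-0.15, 0.11], "p": "0.73"},
      "smi": {"r": -0.01, "ci": [-0.14, 0.12], "p": "0.89"},
      "cefr_art": {"r": -0.07, "ci": [-0.2, 0.06], "p": "0.29"},
      "cefr_pv": {"r": -0.15, "ci": [-0.27, -0.02], "p": "0.02"},
      "cefr_del": {"r": -0.1, "ci": [-0.23, 0.03], "p": "0.12"}
    },
    "meld": {
      "sff": {"r": -0.05, "ci": [-0.18, 0.08], "p": "0.41"},
      "smi": {"r": -0.06, "ci": [-0.19, 0.07], "p": "0.39"},
      "cefr_art": {"r": -0.15, "ci": [-0.28, -0.02], "p": "0.02"},
      "cefr_pv": {"r": -0.21, "ci": [-0.33, -0.08], "p": "0.001"},
      "cefr_del": {"r": -0.17, "ci": [-0.29, -0.03], "p": "0.01"}
    },
    "bmi": {
      "sff": {"r": 0.34, "ci": [0.22, 0.45], "p": "<0.001"},
      "smi": {"r": 0.36, "ci": [0.24, 0.47], "p": "<0.001"},
      "cefr_art": {"r": 0.04, "ci": [-0.09, 0.17], "p": "0.56"},
      "cefr_pv": {"r": 0.02, "ci": [-0.11, 0.15], "p": "0.72"},
      "cefr_del": {"r": 0.05, "ci": [-0.08, 0.18], "p": "0.49"}
    }
  },
  "biomarker_pairs": {
    "sff~cefr_pv": {"r": 0.13, "ci": [0.001, 0.26], "p": "0.04"},
    "sff~cefr_del": {"r": 0.15, "ci": [0.02, 0.27], "p": "0.03"}
  }
}
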