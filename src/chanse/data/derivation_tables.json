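{
  "description": "Published summary statistics of the CHANSE derivation cohort (142 children with suspected appendicitis; 84 appendicitis / 58 none; 52 uncomplicated / 32 complicated). Counts are per-group positives; 'inferred' marks counts reconstructed from the printed per-parameter metrics rather than printed directly.",
  "group_sizes": {
    "diseased": 84,
    "not_diseased": 58,
    "uncomplicated": 52,
    "complicated": 32
  },
  "binary_counts": {
    "male": {"diseased": 52, "not_diseased": 24, "inferred": false},
    "fever": {"diseased": 35, "not_diseased": 20, "inferred": false},
    "anorexia": {"diseased": 49, "not_diseased": 20, "inferred": false},
    "nausea_or_vomiting": {"diseased": 47, "not_diseased": 8, "inferred": false},
    "diarrhea": {"diseased": 19, "not_diseased": 16, "inferred": false},
    "migration": {"diseased": 22, "not_diseased": 15, "inferred": false},
    "leukocytosis": {"diseased": 61, "not_diseased": 22, "inferred": false},
    "left_shift": {"diseased": 59, "not_diseased": 16, "inferred": false},
    "crp_elevated_1": {"diseased": 52, "not_diseased": 22, "inferred": true},
    "crp_elevated_5": {"diseased": 22, "not_diseased": 5, "inferred": false},
    "rlq_tenderness": {"diseased": 72, "not_diseased": 43, "inferred": false},
    "cough_percussion_hopping": {"diseased": 68, "not_diseased": 39, "inferred": false},
    "psoas": {"diseased": 27, "not_diseased": 16, "inferred": false},
    "rovsing": {"diseased": 25, "not_diseased": 7, "inferred": false},
    "obturator": {"diseased": 31, "not_diseased": 18, "inferred": false},
    "heel_drop": {"diseased": 66, "not_diseased": 35, "inferred": false}
  },
  "univariate_printed_or": {
    "male": {"or": 2.302, "ci": [1.162, 4.559]},
    "fever": {"or": 1.357, "ci": [0.678, 2.716]},
    "anorexia": {"or": 2.660, "ci": [1.329, 5.323]},
    "nausea_or_vomiting": {"or": 7.939, "ci": [3.354, 18.794]},
    "diarrhea": {"or": 0.767, "ci": [0.355, 1.657]},
    "migration": {"or": 1.017, "ci": [0.474, 2.181]},
    "leukocytosis": {"or": 4.340, "ci": [2.123, 8.872]},
    "left_shift": {"or": 6.195, "ci": [2.950, 13.008]},
    "crp_elevated_5": {"or": 3.761, "ci": [1.332, 10.620]},
    "rlq_tenderness": {"or": 2.093, "ci": [0.896, 4.887]},
    "cough_percussion_hopping": {"or": 2.071, "ci": [1.056, 4.484]},
    "psoas": {"or": 1.243, "ci": [0.596, 2.595]},
    "rovsing": {"or": 3.087, "ci": [1.233, 7.732]},
    "obturator": {"or": 1.300, "ci": [0.638, 2.647]},
    "heel_drop": {"or": 2.410, "ci": [1.149, 5.053]}
  },
  "parameter_table_printed": {
    "migration": {
      "sensitivity": [0.27, 0.17, 0.37], "specificity": [0.74, 0.61, 0.85],
      "ppv": [0.59, 0.45, 0.72], "npv": [0.41, 0.37, 0.46],
      "plr": [1.02, 0.58, 1.80], "nlr": [0.99, 0.81, 1.21]
    },
    "anorexia": {
      "sensitivity": [0.58, 0.47, 0.69], "specificity": [0.66, 0.52, 0.78],
      "ppv": [0.71, 0.62, 0.78], "npv": [0.52, 0.44, 0.60],
      "plr": [1.69, 1.14, 2.52], "nlr": [0.64, 0.46, 0.87]
    },
    "nausea_or_vomiting": {
      "sensitivity": [0.56, 0.45, 0.67], "specificity": [0.86, 0.75, 0.94],
      "ppv": [0.85, 0.75, 0.92], "npv": [0.57, 0.51, 0.64],
      "plr": [4.06, 2.07, 7.93], "nlr": [0.51, 0.39, 0.66]
    },
    "rlq_tenderness": {
      "sensitivity": [0.86, 0.76, 0.92], "specificity": [0.26, 0.15, 0.39],
      "ppv": [0.63, 0.58, 0.67], "npv": [0.56, 0.39, 0.71],
      "plr": [1.16, 0.97, 1.38], "nlr": [0.55, 0.28, 1.09]
    },
    "cough_percussion_hopping": {
      "sensitivity": [0.81, 0.71, 0.89], "specificity": [0.33, 0.21, 0.46],
      "ppv": [0.64, 0.59, 0.68], "npv": [0.54, 0.40, 0.68],
      "plr": [1.22, 1.02, 1.48], "nlr": [0.56, 0.33, 0.98]
    },
    "fever": {
      "sensitivity": [0.14, 0.8, 0.24], "specificity": [0.91, 0.81, 0.97],
      "ppv": [0.71, 0.47, 0.87], "npv": [0.42, 0.40, 0.45],
      "plr": [1.66, 0.62, 4.45], "nlr": [0.94, 0.83, 1.06]
    },
    "leukocytosis": {
      "sensitivity": [0.73, 0.62, 0.82], "specificity": [0.62, 0.48, 0.74],
      "ppv": [0.73, 0.66, 0.80], "npv": [0.61, 0.51, 0.70],
      "plr": [1.91, 1.34, 2.73], "nlr": [0.44, 0.30, 0.66]
    },
    "left_shift": {
      "sensitivity": [0.70, 0.59, 0.80], "specificity": [0.72, 0.59, 0.83],
      "ppv": [0.79, 0.70, 0.85], "npv": [0.63, 0.54, 0.71],
      "plr": [2.55, 1.64, 3.95], "nlr": [0.41, 0.29, 0.59]
    },
    "crp_elevated_1": {
      "sensitivity": [0.62, 0.51, 0.72], "specificity": [0.62, 0.48, 0.74],
      "ppv": [0.70, 0.62, 0.77], "npv": [0.53, 0.45, 0.61],
      "plr": [1.63, 1.13, 2.36], "nlr": [0.61, 0.44, 0.86]
    },
    "heel_drop": {
      "sensitivity": [0.79, 0.68, 0.87], "specificity": [0.40, 0.27, 0.53],
      "ppv": [0.65, 0.60, 0.70], "npv": [0.56, 0.43, 0.68],
      "plr": [1.30, 1.03, 1.65], "nlr": [0.54, 0.32, 0.91]
    }
  },
  "threshold_table_printed": {
    "chanse": {
      "2": {"sensitivity": 0.88, "specificity": 0.47, "ppv": 0.70, "npv": 0.73, "plr": 1.65, "nlr": 0.26},
      "3": {"sensitivity": 0.69, "specificity": 0.76, "ppv": 0.81, "npv": 0.63, "plr": 2.86, "nlr": 0.41},
      "4": {"sensitivity": 0.51, "specificity": 0.91, "ppv": 0.90, "npv": 0.56, "plr": 5.94, "nlr": 0.53}
    },
    "pas": {
      "6": {"sensitivity": 0.81, "specificity": 0.41, "ppv": 0.67, "npv": 0.60, "plr": 1.38, "nlr": 0.46},
      "7": {"sensitivity": 0.71, "specificity": 0.71, "ppv": 0.78, "npv": 0.63, "plr": 2.44, "nlr": 0.40},
      "8": {"sensitivity": 0.61, "specificity": 0.84, "ppv": 0.85, "npv": 0.60, "plr": 3.91, "nlr": 0.47}
    }
  },
  "continuous_labs": {
    "age_years": {"mean_diseased": 11.3, "sd_diseased": 2.9, "mean_not_diseased": 12.0, "sd_not_diseased": 3.1},
    "body_temp_c": {"mean_diseased": 37.3, "sd_diseased": 0.7, "mean_not_diseased": 37.1, "sd_not_diseased": 0.6},
    "pain_duration_h": {"mean_diseased": 27.6, "sd_diseased": 22.1, "mean_not_diseased": 27.3, "sd_not_diseased": 20.2},
    "wbc_per_ul": {"mean_diseased": 13700.0, "sd_diseased": 5300.0, "mean_not_diseased": 9600.0, "sd_not_diseased": 3900.0},
    "neutrophil_pct": {"mean_diseased": 77.9, "sd_diseased": 14.6, "mean_not_diseased": 63.6, "sd_not_diseased": 15.4},
    "crp_mg_dl": {"mean_diseased": 4.3, "sd_diseased": 9.1, "mean_not_diseased": 1.3, "sd_not_diseased": 2.9}
  },
  "severity_chanse_means": {
    "uncomplicated": {"mean": 3.0, "sd": 1.5},
    "complicated": {"mean": 4.6, "sd": 1.5}
  },
  "auc_printed": {
    "chanse": {"auc": 0.794, "ci": [0.720, 0.867]},
    "pas": {"auc": 0.763, "ci": [0.685, 0.840]}
  }
}
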