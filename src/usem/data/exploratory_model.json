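{
  "description": "Published 13-edge exploratory unified-SEM model of the 9-node DMN. For each directed edge: the lagged->lagged path coefficient per decade cohort (20s..70s) and the reported Pearson correlation of those coefficients with decade.",
  "n_cohorts": 6,
  "cohort_labels": ["20s", "30s", "40s", "50s", "60s", "70s"],
  "edges": [
    {"source": "pC",   "target": "LMFG", "coefficients": [0.37, 0.33, 0.25, 0.20, 0.23, 0.17], "reported_r": -0.93},
    {"source": "pC",   "target": "RIPL", "coefficients": [0.20, 0.29, 0.29, 0.36, 0.34, 0.41], "reported_r": 0.94},
    {"source": "pC",   "target": "LIPL", "coefficients": [0.42, 0.39, 0.38, 0.37, 0.47, 0.44], "reported_r": 0.46},
    {"source": "pC",   "target": "LMTG", "coefficients": [0.39, 0.32, 0.24, 0.27, 0.24, 0.14], "reported_r": -0.93},
    {"source": "pC",   "target": "PCC",  "coefficients": [0.64, 0.61, 0.61, 0.59, 0.62, 0.60], "reported_r": -0.59},
    {"source": "PCC",  "target": "LMTG", "coefficients": [0.30, 0.38, 0.41, 0.43, 0.41, 0.52], "reported_r": 0.91},
    {"source": "PCC",  "target": "RMTG", "coefficients": [0.23, 0.27, 0.35, 0.32, 0.34, 0.42], "reported_r": 0.92},
    {"source": "PCC",  "target": "MPFG", "coefficients": [0.47, 0.52, 0.47, 0.48, 0.41, 0.45], "reported_r": -0.61},
    {"source": "PCC",  "target": "vACC", "coefficients": [0.23, 0.25, 0.24, 0.27, 0.19, 0.18], "reported_r": -0.41,
     "note": "reported_r is internally inconsistent with the coefficient vector (recomputation gives -0.61 on any affine decade axis); both values are non-significant at the |r|>=0.811 criterion"},
    {"source": "MPFG", "target": "vACC", "coefficients": [0.42, 0.39, 0.31, 0.31, 0.44, 0.42], "reported_r": 0.15},
    {"source": "MPFG", "target": "LMFG", "coefficients": [0.24, 0.27, 0.30, 0.36, 0.37, 0.41], "reported_r": 0.99},
    {"source": "LIPL", "target": "RIPL", "coefficients": [0.49, 0.37, 0.27, 0.30, 0.16, 0.08], "reported_r": -0.97},
    {"source": "LMTG", "target": "RMTG", "coefficients": [0.47, 0.36, 0.31, 0.30, 0.25, 0.27], "reported_r": -0.89}
  ]
}
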