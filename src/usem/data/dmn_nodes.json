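{
  "description": "Default-mode-network nodes from a published ALE/MACM meta-analysis; centers of mass in Talairach space (mm).",
  "nodes": [
    {"name": "pC",   "label": "Precuneus",                  "xyz": [-4, -58, 44]},
    {"name": "PCC",  "label": "Posterior Cingulate Cortex", "xyz": [-4, -52, 22]},
    {"name": "vACC", "label": "Ventral Anterior Cingulate", "xyz": [2, 32, -8]},
    {"name": "RIPL", "label": "R Inferior Parietal Lobule", "xyz": [52, -28, 24]},
    {"name": "MPFG", "label": "Medial Prefrontal Gyrus",    "xyz": [-2, 50, 18]},
    {"name": "RMTG", "label": "R Middle Temporal Gyrus",    "xyz": [46, -66, 16]},
    {"name": "LMFG", "label": "L Middle Frontal Gyrus",     "xyz": [-26, 16, 14]},
    {"name": "LIPL", "label": "L Inferior Parietal Lobule", "xyz": [-56, -36, 28]},
    {"name": "LMTG", "label": "L Middle Temporal Gyrus",    "xyz": [-42, -66, 18]}
  ]
}
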