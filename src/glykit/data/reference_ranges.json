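{
  "description": "Healthy, undesirable and abnormal diagnostic ranges for the model physiological parameters and dimensionless numbers, from the n=1198 cohort study.",
  "rows": [
    {"index": "k_js", "process": "Digestive motility", "units": "min^-1",
     "healthy": [0.0198, 0.244], "undesirable": [0.01, 0.0198],
     "abnormal": {"op": "<", "bound": 0.01}},
    {"index": "tau", "process": "Digestive motility", "units": "min",
     "healthy": [72.0, 111.0], "undesirable": [45.0, 72.0],
     "abnormal": {"op": "<", "bound": 45.0}},
    {"index": "Pi_S", "process": "Digestive motility", "units": "-",
     "healthy": [0.396, 47.6], "undesirable": [0.0013, 0.396],
     "abnormal": {"op": "<", "bound": 0.0013}},
    {"index": "k_lg", "process": "Glucose absorption", "units": "min^-1",
     "healthy": [0.00371, 0.602], "undesirable": [0.602, 1.62],
     "abnormal": {"op": ">", "bound": 1.62}},
    {"index": "Pi_N", "process": "Incretin potency", "units": "-",
     "healthy": [0.232, 3.84], "undesirable": [0.000812, 0.232],
     "abnormal": {"op": "<", "bound": 0.000812}},
    {"index": "eta", "process": "Glucose distribution", "units": "L^-3",
     "healthy": [0.0145, 0.178], "undesirable": [0.178, 6.97],
     "abnormal": {"op": ">", "bound": 6.97}},
    {"index": "Pi_D", "process": "Glucose distribution", "units": "-",
     "healthy": [1.2, 15.4], "undesirable": [15.4, 550.0],
     "abnormal": {"op": ">", "bound": 550.0}},
    {"index": "k_xgi", "process": "Tisular glucose uptake", "units": "min^-1 pM^-1",
     "healthy": [9.41e-06, 0.00259], "undesirable": [5.67e-09, 9.41e-06],
     "abnormal": {"op": "<", "bound": 5.67e-09}},
    {"index": "Pi_B", "process": "Tisular glucose uptake", "units": "-",
     "healthy": [0.00204, 159.0], "undesirable": [6.42e-07, 0.00204],
     "abnormal": {"op": "<", "bound": 6.42e-07}},
    {"index": "Pi_X", "process": "Tisular glucose uptake", "units": "-",
     "healthy": [0.00866, 0.395], "undesirable": [3.59e-07, 0.00866],
     "abnormal": {"op": "<", "bound": 3.59e-07}},
    {"index": "Pi_I", "process": "Pancreatic response", "units": "-",
     "healthy": [0.394, 19.0], "undesirable": [0.00871, 0.394],
     "abnormal": {"op": "<", "bound": 0.00871}},
    {"index": "Pi_R", "process": "Hepatic response", "units": "-",
     "healthy": [0.00933, 41.0], "undesirable": [41.0, 134.0],
     "abnormal": {"op": ">", "bound": 134.0}},
    {"index": "G_b", "process": "Effective control levels", "units": "mM",
     "healthy": [4.1, 5.03], "undesirable": [5.03, 5.29],
     "abnormal": {"op": ">", "bound": 5.29}},
    {"index": "I_b", "process": "Effective control levels", "units": "pM",
     "healthy": [13.1, 47.9], "undesirable": [47.9, 68.6],
     "abnormal": {"op": ">", "bound": 68.6}}
  ]
}
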