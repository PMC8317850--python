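{
  "description": "Published summary values from the 11-patient ESWL study cohort used as reproduction checks.",
  "metrics_percent": {
    "accuracy": 63.9,
    "sensitivity": 56.0,
    "specificity": 74.7,
    "ppv": 75.3,
    "npv": 55.2,
    "prevalence": 58.0,
    "detection_rate": 32.5,
    "detection_prevalence": 43.1,
    "balanced_accuracy": 65.4,
    "youden_j": 30.7,
    "no_information_rate": 58.0
  },
  "kappa": 0.2931,
  "efficiency": {
    "relative_treatment_time": 1.94,
    "mishit_ratio_pct": 32.9,
    "mishit_reduction_pct": 67.1,
    "operator_hits_per_min": 45,
    "ai_hits_per_min": 23,
    "pulse_rate": 90
  },
  "pooling": {"chi2": 927.4, "df": 7, "pooled_rate_pct": 50.12},
  "per_patient_bootstrap_pct": {
    "2": [53.4, 51.6, 55.1],
    "4": [59.0, 57.0, 61.0],
    "5": [63.4, 61.6, 65.2],
    "6": [54.7, 53.0, 56.4],
    "7": [47.9, 46.2, 49.5],
    "8": [53.1, 51.5, 54.6],
    "10": [21.3, 20.0, 22.7],
    "11": [89.0, 86.2, 91.7]
  },
  "overall_bootstrap_pct": [55.2, 43.2, 67.3],
  "normality": {"skew_z": -0.005, "kurt_z": 1.73},
  "frame_counts": {
    "n_frames_total": 23212,
    "n_frames_evaluated": 18440,
    "n_focus_annot": 11633,
    "n_direct_annotations": 731
  },
  "bootstrap_defaults": {"frame_level_samples": 5000, "patient_level_samples": 3000}
}
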