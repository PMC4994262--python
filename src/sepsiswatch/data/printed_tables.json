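{
  "version": 1,
  "notes": [
    "Published operating characteristics of a 15-month prospective ED sepsis-alert validation (93,773 encounters, 352 septic).",
    "Quantile columns are the 25th and 75th percentiles (the source table footnote states median and quartiles).",
    "The October 2009 triage-nurse AUC is stored as 0.827: the source print shows 0.627, but the binary-AUC identity (sens 69.0%, FPR 3.6%) and the table's own Min/CV summary rows (min 0.677, CV 0.066) are only consistent with 0.827, so 0.627 is treated as a typographical error.",
    "The per-day maximum-AUC alert burden is stored as 20.33 alerts/day (the stray '%' in the print is ignored)."
  ],
  "constants": {
    "total_encounters": 93773,
    "nonseptic_encounters": 93421,
    "septic_encounters": 352,
    "unique_patients": 58603,
    "study_days": 456,
    "encounters_per_day": 208,
    "prevalence_pct": 0.38,
    "deployed_threshold": 0.05,
    "target_sensitivity": 0.80,
    "fp_per_day_budget": 15.0,
    "target_fpr_pct": 7.2,
    "continuous_auc": 0.953
  },
  "table1": {
    "continuous": {
      "age_years":  {"nonseptic": {"median": 39.6, "q25": 27.3, "q75": 57.1, "availability": 1.00},
                     "septic":    {"median": 60.9, "q25": 51.7, "q75": 73.4, "availability": 1.00}},
      "sbp":        {"nonseptic": {"median": 132.0, "q25": 119.0, "q75": 146.0, "availability": 0.97},
                     "septic":    {"median": 109.0, "q25": 91.0, "q75": 129.0, "availability": 0.97}},
      "dbp":        {"nonseptic": {"median": 77.0, "q25": 68.0, "q75": 86.0, "availability": 0.97},
                     "septic":    {"median": 60.0, "q25": 48.0, "q75": 73.0, "availability": 0.97}},
      "mean_bp":    {"nonseptic": {"median": 95.0, "q25": 86.0, "q75": 105.0, "availability": 0.97},
                     "septic":    {"median": 75.0, "q25": 64.0, "q75": 94.0, "availability": 0.97}},
      "temp_c":     {"nonseptic": {"median": 36.4, "q25": 36.0, "q75": 36.8, "availability": 0.95},
                     "septic":    {"median": 37.7, "q25": 36.6, "q75": 38.7, "availability": 0.96}},
      "hr":         {"nonseptic": {"median": 86.0, "q25": 75.0, "q75": 99.0, "availability": 0.97},
                     "septic":    {"median": 111.0, "q25": 91.0, "q75": 126.0, "availability": 0.98}},
      "wbc_k":      {"nonseptic": {"median": 8.5, "q25": 6.7, "q75": 10.9, "availability": 0.22},
                     "septic":    {"median": 14.3, "q25": 9.8, "q75": 20.6, "availability": 0.53}},
      "lactate":    {"nonseptic": {"median": 1.7, "q25": 1.2, "q75": 2.5, "availability": 0.03},
                     "septic":    {"median": 2.8, "q25": 1.9, "q75": 4.7, "availability": 0.36}}
    },
    "binary": {
      "female": {"nonseptic": 0.582, "septic": 0.537},
      "screen": {"nonseptic": 0.068, "septic": 0.619},
      "flag":   {"nonseptic": 0.031, "septic": 0.543}
    }
  },
  "table2": [
    {"label": "triage_nurse", "cutoff": 1.000, "sens_pct": 54.3, "fpr_pct": 3.1, "auc": 0.756,
     "spec_pct": 96.9, "ppv_pct": 6.1, "npv_pct": 99.8, "fp_per_day": 6.44,
     "inc_tp_nurse": null, "inc_tp_model": null},
    {"label": "sirs_derived", "cutoff": 1.000, "sens_pct": 21.6, "fpr_pct": 0.4, "auc": 0.606,
     "spec_pct": 99.6, "ppv_pct": 17.2, "npv_pct": 99.7, "fp_per_day": 0.80,
     "inc_tp_nurse": 187, "inc_tp_model": 4},
    {"label": "cut05", "cutoff": 0.050, "sens_pct": 76.4, "fpr_pct": 4.7, "auc": 0.859,
     "spec_pct": 95.3, "ppv_pct": 5.8, "npv_pct": 99.9, "fp_per_day": 9.64,
     "inc_tp_nurse": 22, "inc_tp_model": 100},
    {"label": "cut04", "cutoff": 0.040, "sens_pct": 79.0, "fpr_pct": 5.4, "auc": 0.868,
     "spec_pct": 94.6, "ppv_pct": 5.2, "npv_pct": 99.9, "fp_per_day": 11.16,
     "inc_tp_nurse": 18, "inc_tp_model": 105},
    {"label": "sens80", "cutoff": 0.036, "sens_pct": 80.1, "fpr_pct": 5.8, "auc": 0.871,
     "spec_pct": 94.2, "ppv_pct": 4.9, "npv_pct": 99.9, "fp_per_day": 12.03,
     "inc_tp_nurse": 17, "inc_tp_model": 108},
    {"label": "fpc15", "cutoff": 0.026, "sens_pct": 85.2, "fpr_pct": 7.3, "auc": 0.890,
     "spec_pct": 92.7, "ppv_pct": 4.2, "npv_pct": 99.9, "fp_per_day": 15.00,
     "inc_tp_nurse": 13, "inc_tp_model": 122},
    {"label": "max_auc", "cutoff": 0.017, "sens_pct": 89.2, "fpr_pct": 9.9, "auc": 0.897,
     "spec_pct": 90.1, "ppv_pct": 3.3, "npv_pct": 100.0, "fp_per_day": 20.33,
     "inc_tp_nurse": 12, "inc_tp_model": 135},
    {"label": "nrs_fp", "cutoff": 0.097, "sens_pct": 70.2, "fpr_pct": 3.1, "auc": 0.835,
     "spec_pct": 96.9, "ppv_pct": 7.8, "npv_pct": 99.9, "fp_per_day": 6.44,
     "inc_tp_nurse": 32, "inc_tp_model": 88},
    {"label": "nrs_sens", "cutoff": 0.330, "sens_pct": 54.3, "fpr_pct": 1.6, "auc": 0.763,
     "spec_pct": 98.4, "ppv_pct": 11.4, "npv_pct": 99.8, "fp_per_day": 3.27,
     "inc_tp_nurse": 64, "inc_tp_model": 64}
  ],
  "table3": {
    "columns": ["label", "encounters", "per_day", "sepsis", "rate_pct", "cont_auc",
                "model_sens_pct", "model_fpr_pct", "model_fp_per_day", "model_auc",
                "nurse_sens_pct", "nurse_fpr_pct", "nurse_fp_per_day", "nurse_auc"],
    "month_days": [30, 31, 30, 31, 31, 30, 31, 30, 31, 31, 28, 31, 30, 31, 30],
    "months": [
      ["200904", 6279, 209, 22, 0.35, 0.957, 72.7, 4.5, 9.43, 0.841, 68.2, 2.7, 5.69, 0.827],
      ["200905", 6583, 212, 21, 0.32, 0.952, 76.2, 5.2, 11.00, 0.855, 38.1, 2.8, 5.86, 0.677],
      ["200906", 6860, 229, 26, 0.38, 0.963, 88.5, 5.6, 12.82, 0.914, 50.0, 4.1, 9.27, 0.730],
      ["200907", 6736, 217, 22, 0.33, 0.974, 72.7, 4.6, 10.03, 0.841, 50.0, 2.3, 4.92, 0.739],
      ["200908", 6439, 208, 22, 0.34, 0.934, 72.7, 4.3, 8.97, 0.842, 45.5, 2.5, 5.18, 0.715],
      ["200909", 6352, 212, 25, 0.39, 0.961, 64.0, 4.6, 9.64, 0.797, 40.0, 2.6, 5.59, 0.687],
      ["200910", 6451, 208, 29, 0.45, 0.957, 86.2, 4.5, 9.43, 0.908, 69.0, 3.6, 7.49, 0.827],
      ["200911", 5975, 199, 25, 0.42, 0.953, 76.0, 4.5, 8.94, 0.858, 56.0, 3.5, 7.00, 0.762],
      ["200912", 5753, 186, 27, 0.47, 0.944, 81.5, 4.7, 8.75, 0.884, 51.9, 3.0, 5.51, 0.744],
      ["201001", 6206, 200, 27, 0.44, 0.932, 77.8, 4.2, 8.49, 0.868, 44.4, 3.4, 6.71, 0.705],
      ["201002", 5568, 199, 22, 0.40, 0.948, 68.2, 5.1, 10.11, 0.815, 63.6, 3.5, 6.96, 0.801],
      ["201003", 6250, 202, 17, 0.27, 0.965, 82.4, 4.6, 9.28, 0.889, 70.6, 3.8, 7.63, 0.834],
      ["201004", 5885, 196, 27, 0.46, 0.947, 77.8, 4.4, 8.71, 0.867, 55.6, 2.9, 5.73, 0.763],
      ["201005", 6184, 199, 17, 0.27, 0.969, 76.5, 4.9, 9.80, 0.858, 58.8, 3.4, 6.79, 0.777],
      ["201006", 6252, 208, 23, 0.37, 0.931, 69.6, 4.4, 9.10, 0.826, 56.5, 3.0, 6.19, 0.768]
    ],
    "summary": {
      "min": {"rate_pct": 0.27, "cont_auc": 0.931, "model_sens_pct": 64.0, "model_fpr_pct": 4.2,
              "model_fp_per_day": 8.49, "model_auc": 0.797, "nurse_sens_pct": 38.1,
              "nurse_fpr_pct": 2.3, "nurse_fp_per_day": 4.92, "nurse_auc": 0.677},
      "max": {"rate_pct": 0.47, "cont_auc": 0.974, "model_sens_pct": 88.5, "model_fpr_pct": 5.6,
              "model_fp_per_day": 12.82, "model_auc": 0.914, "nurse_sens_pct": 70.6,
              "nurse_fpr_pct": 4.1, "nurse_fp_per_day": 9.27, "nurse_auc": 0.834},
      "cv": {"rate_pct": 16.72, "cont_auc": 0.014, "model_sens_pct": 8.7, "model_fpr_pct": 7.9,
             "model_fp_per_day": 0.11, "model_auc": 0.038, "nurse_sens_pct": 18.8,
             "nurse_fpr_pct": 16.4, "nurse_fp_per_day": 0.18, "nurse_auc": 0.066}
    }
  }
}
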