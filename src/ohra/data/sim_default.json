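{
  "comment": "Four-group benzene printing-industry survey configuration. Concentration entries give either calibration targets (group mean mg/m^3, exceedance fraction over the 6 mg/m^3 OEL) or explicit (mu, sigma) for fully censored groups; prevalences are the surveyed category frequencies.",
  "groups": [
    {
      "group": "printing",
      "n_segs": 7,
      "conc": {"target_mean": 4.67, "target_exceed_frac": 0.2857142857142857, "limit": 6.0},
      "lod": 0.02,
      "stel_lod": 0.07,
      "usage": {"mean_daily_kg": 104.7, "log_sd": 1.5},
      "hours_choices": [[8, 0.65], [10, 0.35]],
      "days_choices": [[5, 0.7], [6, 0.3]],
      "duration_choices": [[160, 0.25], [200, 0.5], [240, 0.25]],
      "n_workers_range": [4, 30],
      "control_prevalences": {
        "automation": {"full": 0.5714285714285714, "semi": 0.0, "manual": 0.42857142857142855},
        "ventilation": {"local_exhaust": 0.5714285714285714, "general": 0.42857142857142855, "none": 0.0},
        "ppe_equipped": 0.8571428571428571,
        "ppe_worn_given_equipped": 1.0,
        "first_aid": 0.42857142857142855,
        "emergency_measures": {"complete": 0.42857142857142855, "partial": 0.5714285714285714, "none": 0.0},
        "oh_management": {"good": 0.42857142857142855, "poor": 0.5714285714285714, "lacking": 0.0}
      }
    },
    {
      "group": "cleaning",
      "n_segs": 3,
      "conc": {"mu": -6.2146, "sigma": 0.8},
      "lod": 0.02,
      "stel_lod": null,
      "usage": {"mean_daily_kg": 68.0, "log_sd": 0.8},
      "hours_choices": [[8, 0.65], [10, 0.35]],
      "days_choices": [[5, 0.7], [6, 0.3]],
      "duration_choices": [[160, 0.4], [200, 0.6]],
      "n_workers_range": [5, 6],
      "control_prevalences": {
        "automation": {"full": 0.0, "semi": 0.6666666666666666, "manual": 0.3333333333333334},
        "ventilation": {"local_exhaust": 0.0, "general": 1.0, "none": 0.0},
        "ppe_equipped": 1.0,
        "ppe_worn_given_equipped": 0.6666666666666666,
        "first_aid": 0.3333333333333333,
        "emergency_measures": {"complete": 0.3333333333333334, "partial": 0.6666666666666666, "none": 0.0},
        "oh_management": {"good": 0.6666666666666666, "poor": 0.3333333333333334, "lacking": 0.0}
      }
    },
    {
      "group": "pasting",
      "n_segs": 6,
      "conc": {"target_mean": 3.47, "target_exceed_frac": 0.16666666666666666, "limit": 6.0},
      "lod": 0.02,
      "stel_lod": null,
      "usage": {"mean_daily_kg": 523.1, "log_sd": 1.8},
      "hours_choices": [[8, 0.65], [10, 0.35]],
      "days_choices": [[5, 0.3], [6, 0.7]],
      "duration_choices": [[160, 0.55], [240, 0.45]],
      "n_workers_range": [5, 84],
      "control_prevalences": {
        "automation": {"full": 0.16666666666666666, "semi": 0.3333333333333333, "manual": 0.5},
        "ventilation": {"local_exhaust": 0.16666666666666666, "general": 0.8333333333333334, "none": 0.0},
        "ppe_equipped": 0.8333333333333334,
        "ppe_worn_given_equipped": 0.8,
        "first_aid": 0.3333333333333333,
        "emergency_measures": {"complete": 0.3333333333333333, "partial": 0.6666666666666667, "none": 0.0},
        "oh_management": {"good": 0.5, "poor": 0.5, "lacking": 0.0}
      }
    },
    {
      "group": "packaging",
      "n_segs": 3,
      "conc": {"mu": -6.2146, "sigma": 0.8},
      "lod": 0.02,
      "stel_lod": 0.07,
      "usage": {"mean_daily_kg": 14.3, "log_sd": 1.2},
      "hours_choices": [[8, 0.65], [10, 0.35]],
      "days_choices": [[5, 0.3], [6, 0.7]],
      "duration_choices": [[160, 0.54], [240, 0.46]],
      "n_workers_range": [6, 44],
      "control_prevalences": {
        "automation": {"full": 0.3333333333333333, "semi": 0.0, "manual": 0.6666666666666667},
        "ventilation": {"local_exhaust": 0.0, "general": 0.6666666666666667, "none": 0.3333333333333333},
        "ppe_equipped": 1.0,
        "ppe_worn_given_equipped": 1.0,
        "first_aid": 1.0,
        "emergency_measures": {"complete": 1.0, "partial": 0.0, "none": 0.0},
        "oh_management": {"good": 1.0, "poor": 0.0, "lacking": 0.0}
      }
    }
  ]
}
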