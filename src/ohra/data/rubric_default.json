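{
  "lod": 0.02,
  "hazard_band_map": {
    "R36": "A",
    "R38": "A",
    "R65": "A",
    "R66": "A",
    "R67": "A",
    "R20": "B",
    "R21": "B",
    "R22": "B",
    "R11": "B",
    "R23": "C",
    "R24": "C",
    "R25": "C",
    "R34": "C",
    "R35": "C",
    "R37": "C",
    "R41": "C",
    "R43": "C",
    "R26": "D",
    "R27": "D",
    "R28": "D",
    "R40": "D",
    "R48/23": "D",
    "R48/24": "D",
    "R48/25": "D",
    "R48/23/24/25": "D",
    "R60": "D",
    "R61": "D",
    "R62": "D",
    "R63": "D",
    "R45": "E",
    "R46": "E",
    "R49": "E",
    "R42": "E",
    "R42/43": "E"
  },
  "coshh_risk_matrix": {
    "A": [
      1,
      1,
      1,
      2
    ],
    "B": [
      1,
      1,
      2,
      2
    ],
    "C": [
      1,
      2,
      3,
      3
    ],
    "D": [
      2,
      3,
      3,
      4
    ],
    "E": [
      4,
      4,
      4,
      4
    ]
  },
  "exposure_band_matrix": {
    "low": {
      "small": 1,
      "medium": 1,
      "large": 2
    },
    "medium": {
      "small": 1,
      "medium": 2,
      "large": 3
    },
    "high": {
      "small": 2,
      "medium": 3,
      "large": 4
    }
  },
  "volatility_vp_high_kpa": 10.0,
  "volatility_bp_low_c": 150.0,
  "operating_temp_c": 25.0,
  "quantity_medium_min_kg": 1.0,
  "quantity_large_min_kg": 1000.0,
  "er_ratio_bands": {
    "edges": [
      0.1,
      0.5,
      1.0,
      2.0
    ],
    "closed": "left",
    "scores": null
  },
  "ei_numeric": {
    "vapor_pressure": {
      "edges": [
        0.1,
        1.0,
        5.0,
        25.0
      ],
      "closed": "right",
      "scores": null
    },
    "weekly_usage": {
      "edges": [
        1.0,
        10.0,
        100.0,
        1000.0
      ],
      "closed": "left",
      "scores": null
    },
    "daily_usage": {
      "edges": [
        1.0,
        10.0,
        100.0,
        1000.0
      ],
      "closed": "left",
      "scores": null
    },
    "weekly_hours": {
      "edges": [
        8.0,
        16.0,
        24.0,
        40.0
      ],
      "closed": "left",
      "scores": null
    },
    "daily_hours": {
      "edges": [
        2.0,
        4.0,
        6.0,
        8.0
      ],
      "closed": "right",
      "scores": null
    },
    "e_over_oel": {
      "edges": [
        0.1,
        0.5,
        1.0,
        2.0
      ],
      "closed": "left",
      "scores": null
    }
  },
  "ei_categorical": {
    "ventilation": {
      "local_exhaust": 2,
      "general": 4,
      "none": 5
    },
    "automation": {
      "full": 1,
      "semi": 3,
      "manual": 5
    },
    "ppe": {
      "worn": 1,
      "equipped": 3,
      "none": 5
    },
    "first_aid": {
      "yes": 1,
      "no": 5
    },
    "emergency_measures": {
      "complete": 1,
      "partial": 3,
      "none": 5
    },
    "oh_management": {
      "good": 1,
      "poor": 3,
      "lacking": 5
    }
  },
  "hr_iarc": {
    "1": 5,
    "2A": 4,
    "2B": 3,
    "3": 2
  },
  "hr_acgih": {
    "A1": 5,
    "A2": 4,
    "A3": 3,
    "A4": 2,
    "A5": 1
  },
  "hr_ld50_bands": {
    "edges": [
      25.0,
      200.0,
      2000.0,
      5000.0
    ],
    "closed": "left",
    "scores": [
      5,
      4,
      3,
      2,
      1
    ]
  },
  "hr_lc50_bands": {
    "edges": [
      200.0,
      2000.0,
      20000.0,
      50000.0
    ],
    "closed": "left",
    "scores": [
      5,
      4,
      3,
      2,
      1
    ]
  },
  "rounding": "half_up_nearest_int",
  "epa_ec_mode": "direct",
  "life_expectancy_years": 70.0,
  "days_per_year_rule": "weeks52",
  "coshh_labels": {
    "1": "low",
    "2": "medium",
    "3": "high",
    "4": "very high"
  },
  "risk_labels": {
    "1": "negligible",
    "2": "low",
    "3": "medium",
    "4": "high",
    "5": "very high"
  }
}
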