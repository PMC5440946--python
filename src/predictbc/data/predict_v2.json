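{
  "schema_version": 1,
  "name": "predict-v2-breast",
  "description": "PREDICT v2 breast cancer model: fractional-polynomial prognostic terms and smoothed baseline log cumulative hazards, refit on the East Anglia registry cohort (1999-2003).",
  "er_negative": [
    {"name": "age", "variable": "age", "power": 1, "shift": 0.0, "scale": 1.0, "log_times": false, "center": 56.325, "coefficient": 0.00894},
    {"name": "size", "variable": "size_mm", "power": 0.5, "shift": 0.0, "scale": 100.0, "log_times": false, "center": 0.5090, "coefficient": 2.109},
    {"name": "nodes", "variable": "nodes", "power": -0.5, "shift": 1.0, "scale": 10.0, "log_times": false, "center": 1.72, "coefficient": -0.705},
    {"name": "grade", "variable": "grade", "power": 1, "shift": 0.0, "scale": 1.0, "log_times": false, "center": 0.0, "coefficient": 0.259}
  ],
  "er_positive": [
    {"name": "age_1", "variable": "age", "power": -2, "shift": 0.0, "scale": 10.0, "log_times": false, "center": 0.0287, "coefficient": 34.53},
    {"name": "age_2", "variable": "age", "power": -2, "shift": 0.0, "scale": 10.0, "log_times": true, "center": 0.0510, "coefficient": -34.20},
    {"name": "size", "variable": "size_mm", "power": 0, "shift": 0.0, "scale": 100.0, "log_times": false, "center": -1.5452, "coefficient": 0.7531},
    {"name": "nodes", "variable": "nodes", "power": 0, "shift": 1.0, "scale": 10.0, "log_times": false, "center": -1.3876, "coefficient": 0.7069},
    {"name": "grade", "variable": "grade", "power": 1, "shift": 0.0, "scale": 1.0, "log_times": false, "center": 0.0, "coefficient": 0.7467},
    {"name": "screen", "variable": "screen", "power": 1, "shift": 0.0, "scale": 1.0, "log_times": false, "center": 0.0, "coefficient": -0.2763}
  ],
  "other_mortality": [
    {"name": "age", "variable": "age", "power": 2, "shift": 0.0, "scale": 10.0, "log_times": false, "center": 34.234, "coefficient": 0.0698}
  ],
  "baselines": {
    "breast_er_negative": {
      "intercept": -1.156,
      "terms": [
        {"power": -2, "log_times": false, "coefficient": 0.4707},
        {"power": -1, "log_times": false, "coefficient": -3.514}
      ]
    },
    "breast_er_positive": {
      "intercept": 0.7424,
      "terms": [
        {"power": -0.5, "log_times": false, "coefficient": -7.530},
        {"power": -0.5, "log_times": true, "coefficient": -1.813}
      ]
    },
    "other": {
      "intercept": -6.053,
      "terms": [
        {"power": 0, "log_times": false, "coefficient": 1.080},
        {"power": 0.5, "log_times": false, "coefficient": 0.3255}
      ]
    }
  },
  "treatments": {
    "hormone": {
      "log_hr": -0.386,
      "applies_to": ["breast_er_positive"],
      "source": "EBCTCG trial meta-analysis (adjuvant tamoxifen, ~RR 0.68); external configuration value, not estimated from the registry refit"
    },
    "chemotherapy": {
      "log_hr": -0.248,
      "applies_to": ["breast_er_negative", "breast_er_positive"],
      "source": "EBCTCG trial meta-analysis (anthracycline-based chemotherapy, ~RR 0.78); external configuration value, not estimated from the registry refit"
    }
  }
}
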