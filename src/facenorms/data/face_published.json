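{
  "schema_version": 1,
  "name": "FACE test published norms (Italian normative sample, n = 229)",
  "n": 229,
  "age_coef": 0.0723,
  "center_age": 53.275,
  "sqrt_edu_coef": -1.6493,
  "center_sqrt_edu": 3.595,
  "es_intervals": {
    "es0_max": 22.685,
    "es1_max": 24.611,
    "es2_max": 27.159,
    "es3_max": 29.491,
    "es4_min": 29.492
  },
  "outer_limit": 22.685,
  "inner_limit": 24.244,
  "score_range": [0, 36],
  "grid_ages": [20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85],
  "grid_educations": [5, 8, 13, 17],
  "grid_min_age": {"5": 60, "8": 40, "13": 20, "17": 20}
}
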