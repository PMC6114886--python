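{
  "name": "clinical-score-example",
  "shape": "confirm",
  "comment": "Example coefficient set with the CONFIRM clinical-score covariate structure (age, sex, chest-pain type, diabetes, hypertension, family history, smoking; no calcium term). Coefficients are illustrative defaults used by the test suite and the synthetic generator; substitute the published values via config to score a real cohort.",
  "intercept": -6.2,
  "link": "logistic",
  "ptp_scale": "probability",
  "terms": [
    {"covariate": "age_linear", "coefficient": 0.062},
    {"covariate": "sex_male", "coefficient": 1.25},
    {"covariate": "chest_pain_typical", "coefficient": 1.95},
    {"covariate": "chest_pain_atypical", "coefficient": 0.75},
    {"covariate": "diabetes", "coefficient": 0.40},
    {"covariate": "hypertension", "coefficient": 0.35},
    {"covariate": "family_history", "coefficient": 0.30},
    {"covariate": "smoking", "coefficient": 0.55}
  ]
}
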