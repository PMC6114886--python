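{
  "name": "calcium-extended-example",
  "shape": "gem",
  "comment": "Example coefficient set with the Genders extended model (GEM) covariate structure (age, sex, chest-pain type, dyslipidaemia, diabetes, hypertension, smoking, plus log(CCS+1)). Coefficients are illustrative defaults used by the test suite and the synthetic generator; substitute the published low-prevalence-setting values via config to score a real cohort.",
  "intercept": -7.1,
  "link": "logistic",
  "ptp_scale": "probability",
  "terms": [
    {"covariate": "age_linear", "coefficient": 0.055},
    {"covariate": "sex_male", "coefficient": 1.15},
    {"covariate": "chest_pain_typical", "coefficient": 1.85},
    {"covariate": "chest_pain_atypical", "coefficient": 0.70},
    {"covariate": "diabetes", "coefficient": 0.35},
    {"covariate": "hypertension", "coefficient": 0.30},
    {"covariate": "hyperlipidemia", "coefficient": 0.30},
    {"covariate": "smoking", "coefficient": 0.50},
    {"covariate": "ccs_transform", "coefficient": 0.46,
     "transform_params": {"kind": "log", "shift": 1.0, "base": "e"}}
  ]
}
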