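{
  "name": "Mayo Clinic model for incidental pulmonary nodules",
  "citation": "Swensen SJ, Silverstein MD, Ilstrup DM, Schleck CD, Edell ES. The probability of malignancy in solitary pulmonary nodules. Arch Intern Med 1997;157(8):849-855.",
  "note": "p = exp(x)/(1+exp(x)); covariates: age in years, ever-smoker 0/1, prior extrathoracic cancer (>5 years before) 0/1, nodule diameter in mm, spiculation 0/1, upper-lobe location 0/1.",
  "intercept": -6.8272,
  "terms": [
    {"covariate": "age_years", "coefficient": 0.0391, "transform": "linear"},
    {"covariate": "ever_smoker", "coefficient": 0.7917, "transform": "linear"},
    {"covariate": "prior_extrathoracic_cancer", "coefficient": 1.3388, "transform": "linear"},
    {"covariate": "diameter_mm", "coefficient": 0.1274, "transform": "linear"},
    {"covariate": "spiculation", "coefficient": 1.0407, "transform": "linear"},
    {"covariate": "upper_lobe", "coefficient": 0.7838, "transform": "linear"}
  ]
}
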