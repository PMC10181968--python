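{
  "name": "Brock University (PanCan) model, parsimonious variant with spiculation",
  "citation": "McWilliams A, Tammemagi MC, Mayo JR, et al. Probability of cancer in pulmonary nodules detected on first screening CT. N Engl J Med 2013;369(10):910-919.",
  "note": "Parsimonious covariate set: sex, nodule size (power transform of the largest diameter in mm), nodule type, upper-lobe location, nodule count, spiculation. Coefficient values follow the published PanCan model for these terms; this file is the auditable, replaceable source of the constants.",
  "intercept": -6.7892,
  "terms": [
    {"covariate": "sex", "coefficient": 0.6011, "transform": "indicator", "level": "female"},
    {"covariate": "diameter_mm", "coefficient": -5.3854, "transform": "brock_size"},
    {"covariate": "nodule_type", "coefficient": 0.377, "transform": "indicator", "level": "part_solid"},
    {"covariate": "nodule_type", "coefficient": -0.1276, "transform": "indicator", "level": "ggo"},
    {"covariate": "upper_lobe", "coefficient": 0.6581, "transform": "linear"},
    {"covariate": "nodule_count", "coefficient": -0.0824, "transform": "center", "center": 4},
    {"covariate": "spiculation", "coefficient": 0.7729, "transform": "linear"}
  ]
}
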