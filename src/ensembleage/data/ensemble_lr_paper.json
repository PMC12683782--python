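{
  "clock_names": ["AltumAge", "Han2020", "Hannum", "Horvath", "SkinBlood", "PhenoAge", "YingCausAge", "Zhang2019"],
  "weights": [0.34, -0.21, -0.52, 0.28, 0.19, -0.02, -0.09, 0.56],
  "intercept": 19.28,
  "alpha": 0.1,
  "provenance": "Published EnsembleLR meta-model: ridge (L2, alpha=0.1) stacking of eight base clocks, trained on SMOTE-rebalanced GTEx EPIC data with an 80/20 split. Version 1."
}
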