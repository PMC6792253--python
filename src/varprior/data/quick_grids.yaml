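# Reduced tuning lattice for desk-scale runs: one or two configurations per
# family, centered on each family's robust defaults.  The full default
# lattice lives in grids.yaml.
weighted_forest:
  n_estimators: [100]
  max_depth: [8, null]
weighted_logistic:
  C: [0.1, 1.0]
balanced_forest:
  n_estimators: [100]
  max_depth: [null]
undersampled_boost_ensemble:
  n_estimators: [10]
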