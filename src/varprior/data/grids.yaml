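# Default hyperparameter grids for exhaustive search under stratified
# 10-fold cross-validation.  Edit freely; `varprior train --grids` accepts
# any file with this shape.  null max_depth means unlimited depth.
weighted_forest:
  n_estimators: [100, 200, 500]
  max_depth: [4, 8, null]
weighted_logistic:
  C: [0.01, 0.1, 1, 10]
balanced_forest:
  n_estimators: [100, 200, 500]
  max_depth: [4, 8, null]
undersampled_boost_ensemble:
  n_estimators: [10, 50]
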