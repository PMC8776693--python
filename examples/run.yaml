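# Example ofrad run configuration.
#
#   ofrad simulate --config examples/run.yaml
#   ofrad extract  --config examples/run.yaml
#   ofrad evaluate --config examples/run.yaml
#   ofrad report   --config examples/run.yaml
seed: 11
out_dir: ofrad_run
normalization: zscore        # minmax | zscore
scheme: fivefold             # fivefold | leave_one_institution_out | three_institution_holdout
selection_k: 10
selection_threshold: 0.7
n_boot: 2000
cohort:
  n_patients: 80
  image_shape: [48, 48, 48]
  volume_range_ml: [3.0, 180.0]
  texture_effect_size: 0.75
model:
  family: lasso              # lasso | ridge | naive_bayes | random_forest
  design: combined           # clinical_only | radiomics_only | combined
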