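# Demo pipeline: synthetic cohort with planted local-control (PT) and
# regional (LN) effects, strong enough to be recoverable at demo scale.
out_dir: runs/demo
seed: 11
train_fraction: 0.64
n_eval_boot: 50
synth:
  n_patients: 110
  artifact_fraction: 0.1
truth:
  planted_lc:
    - [pt_shape_elongation, 1.8]
    - [pt_intensity_skewness, 1.4]
  planted_regional:
    - [ln_shape_major_axis, 2.0]
    - [ln_shape_thickness_sd, 1.2]
  baseline_lc_rate: 0.009
  baseline_regional_rate: 0.009
selection:
  n_bootstrap: 100
lasso:
  n_bootstrap: 30
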