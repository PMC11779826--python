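# Example pipeline configuration for `dualrisk run-all --config ...`.
# Exactly one of `generative` / `cohort_path` may be present.
generative: default        # the reference synthetic scenario
n: 20000                   # cohort size to draw
split_ratios: [0.64, 0.16, 0.20]
net:                       # omit to infer input_dim from the features
  input_dim: 10
  hidden_width: 128
  n_residual_blocks: 2
  dropout_rate: 0.25
train:
  learning_rate: 0.01
  momentum: 0.9
  batch_size: 256
  max_epochs: 200
  patience: 10
anchor: dual_system_use    # exposure feature for interaction scoring
scale: logit               # probability | logit
bootstrap_B: 0             # set to 200 for publication-style intervals
seed: 0
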