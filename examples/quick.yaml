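# Quick end-to-end pipeline: 3 synthetic walking styles, ~1 min on one CPU.
#   wristgait run --config examples/quick.yaml --out results/quick/
sim:
  n_classes: 3
  n_subjects: 4
  duration_s: 30.0
data:
  T: 100
  test_fraction: 0.25
  val_fraction: 0.2
model:
  arch: lstm_att
  hidden_size: 32
train:
  batch_size: 32
  max_epochs: 40
  early_stop_patience: 10
seed: 3
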