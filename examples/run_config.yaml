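# Desk-scale end-to-end run: mitoscore run --config examples/run_config.yaml --out rundir
# Profile "paper" switches to the full-resolution recipe (2048-px fields,
# 224-px inputs, 200 epochs, batch 128, lr 1e-4).
profile: desk
seed: 0
simulate:
  n_fields_per_class: 30
  field_size_px: 512
train:
  tasks: [CCCP-NC, CCCP-FL3-NC]
  epochs: 10
score:
  rounds: 100
  k: 4
evaluate:
  n_folds: 5
  test_fold: 0
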