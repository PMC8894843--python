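# Example pipeline configuration: full original-vs-filtered comparison
# on a synthetic Hetionet-like graph with planted treats structure.
# Run with: kgfilter run --config example_synthetic.yaml --out run_dir
dataset:
  synthetic:
    seed: 1
preprocess:
  head_type: Compound
  tail_type: Disease
  keep_relations: [treats]
split:
  target_relation: treats
  valid_fraction: 0.125
  test_fraction: 0.125
  seed: 101
filter:
  # desk-scale walker parameters; full-scale defaults are 1000/100/5000
  starts_per_source: 30
  concat_target_length: 30
  n_concat_per_metapath: 300
  seed: 201
train:
  model: distmult
  dimension: 32
  epochs_max: 60
  seed: 301
evaluate:
  which: test
  baseline_repetitions: 100
diagnose:
  n_samples: 20000
  batch_size: 2000
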