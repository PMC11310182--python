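# Demo pipeline: simulate a synthetic pathway log, remove noise variants,
# sequentialize with the shipped rules, and discover a model in three
# cumulative batches (most frequent variants first).
input:
  simulate:
    n_cases: 200
    p_truncate: 0.05
    p_singleton: 0.05
    p_violation: 0.1
output_dir: scratch/demo_run
filters:
  - predicate: default_noise
    mode: remove
rules: default
discovery:
  order: frequency
  batches: [0.2, 0.4, 0.4]
seed: 42
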