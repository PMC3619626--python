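# Dense-world control comparison: mean learning curves, per-world
# embodiment indices and structural metrics from one master seed.
world_class: dense
n_worlds: 50
strategies: [random, unembodied, pig-greedy, pig-vi]
eval_every: 10
master_seed: 0
compute_metrics: true
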