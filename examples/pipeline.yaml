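# End-to-end pipeline config: synthetic input, small selection grid.
# Run from the repository root:  traceclust run-all --config examples/pipeline.yaml
output_dir: scratch/run
synthetic: examples/synthetic_config.yaml
removal_list: default
min_weekly_events: 25
topic_range: [2, 6]
n_inits: 3
master_seed: 7
k: 3
# theme_map_path: examples/theme_map_17topics.yaml   # for a 17-topic model
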