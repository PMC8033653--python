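# Study-default pipeline configuration: 6-hour windows, minimum support 5,
# subgraph sizes 2-6, three components, 80:20 mortality-stratified split.
n_patients: 300
interval: 6
min_support: 5
min_size: 2
max_size: 6
clip: 4
k: 3
n_consensus_runs: 30
top_n: 100
threshold: 1.0
split_ratio: 0.8
test_size: 0.2
seed: 0
out_dir: sanmf_run
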