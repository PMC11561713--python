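seed	2024
n_taxa	50
birth_rate	1.0
death_rate	0.2
max_size	20
n_subsets	6
subset_sizes	13,12,17,18,16,14
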