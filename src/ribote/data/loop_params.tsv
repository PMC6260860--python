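param	value
hairpin_base	5.0
hairpin_per_nt	0.15
interior_base	3.0
interior_per_nt	0.3
multi_base	4.6
multi_branch	0.4
multi_unpaired	0.1
max_interior	10
min_hairpin	3
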