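key	value
total_snps	17316
target_snps	4269
target_length_bp	614000
min_read_depth	10
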