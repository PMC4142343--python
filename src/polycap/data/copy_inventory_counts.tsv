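key	value
n_genes	30
n_detected	160
n_full_length	124
n_partial	17
n_nonfunctional	23
n_lost	9
n_duplicated	28
n_nonfunctional_duplicated	23
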