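genotype	total_hom	total_het	target_hom	target_het
25629-3	2772	5259	546	1145
Silona	3974	4116	990	599
Campino	4730	4283	1351	813
Magres Pajberg	5849	4836	1538	771
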