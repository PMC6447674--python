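feature	previous_count	new_count
genes_and_pseudogenes	27328	32471
protein_coding	24290	25898
non_coding	2468	5149
pseudogenes	443	1238
mrnas	44123	46160
mrnas_fully_supported	41957	43159
non_coding_rnas	3192	6209
cdss	44263	46358
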