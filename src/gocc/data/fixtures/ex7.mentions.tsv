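# sent_id	start	end	type	norm_id
ex7.s1	0	6	protein	GID:Fbxo45
ex7.s1	22	27	protein	GID:Par-4
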