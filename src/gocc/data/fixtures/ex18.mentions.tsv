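# sent_id	start	end	type	norm_id
ex18.s1	0	4	protein	GID:CD47
ex18.s1	11	16	protein	GID:TSP-1
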