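# sent_id	start	end	type	norm_id
ex2.s1	0	4	protein	GID:Mad1
ex2.s1	20	23	protein	GID:Max
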