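# sent_id	start	end	type	norm_id
ex15.s1	0	4	protein	GID:Ku70
ex15.s1	9	13	protein	GID:Ku80
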