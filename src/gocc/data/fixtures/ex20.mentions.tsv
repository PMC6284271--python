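# sent_id	start	end	type	norm_id
ex20.s1	0	5	protein	GID:CAR-1
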