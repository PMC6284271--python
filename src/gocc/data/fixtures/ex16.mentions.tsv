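# sent_id	start	end	type	norm_id
ex16.s1	0	8	protein	GID:Survivin
ex16.s1	24	32	protein	GID:Borealin
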