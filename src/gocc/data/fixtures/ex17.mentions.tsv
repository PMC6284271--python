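# sent_id	start	end	type	norm_id
ex17.s1	0	5	protein	GID:Hsp70
ex17.s1	28	33	protein	GID:Hsp40
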