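# sent_id	start	end	type	norm_id
cd3.s1	16	19	protein	GID:CD3
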