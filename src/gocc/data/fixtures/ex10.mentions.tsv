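# sent_id	start	end	type	norm_id
ex10.s1	21	24	protein	GID:Sp1
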