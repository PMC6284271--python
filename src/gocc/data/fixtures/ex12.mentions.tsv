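# sent_id	start	end	type	norm_id
ex12.s1	29	33	protein	GID:Gcn5
ex12.s1	38	42	protein	GID:Ada2
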