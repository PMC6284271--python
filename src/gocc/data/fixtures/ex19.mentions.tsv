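# sent_id	start	end	type	norm_id
ex19.s1	10	15	protein	GID:Bmh1p
ex19.s1	20	25	protein	GID:Bmh2p
ex19.s1	41	47	protein	GID:Ste20p
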