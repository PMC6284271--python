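# sent_id	start	end	type	norm_id
ex3.s1	54	58	protein	GID:Rpg1
ex3.s1	60	64	protein	GID:Nip1
ex3.s1	66	70	protein	GID:Prt1
ex3.s1	72	77	protein	GID:Tif34
ex3.s1	83	88	protein	GID:Tif35
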