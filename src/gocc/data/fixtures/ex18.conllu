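# sent_id = ex18.s1
# text = CD47 binds TSP-1 and inhibits angiogenesis.
1	CD47	cd47	PROPN	_	_	2	nsubj	_	_
2	binds	bind	VERB	_	_	0	root	_	_
3	TSP-1	tsp-1	PROPN	_	_	2	dobj	_	_
4	and	and	CCONJ	_	_	2	cc	_	_
5	inhibits	inhibit	VERB	_	_	2	conj:and	_	_
6	angiogenesis	angiogenesis	NOUN	_	_	5	dobj	_	_
7	.	.	PUNCT	_	_	2	punct	_	_

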