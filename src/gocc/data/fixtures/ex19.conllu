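# sent_id = ex19.s1
# text = Moreover, Bmh1p and Bmh2p associate with Ste20p in vivo.
1	Moreover	moreover	ADV	_	_	6	advmod	_	_
2	,	,	PUNCT	_	_	6	punct	_	_
3	Bmh1p	bmh1p	PROPN	_	_	6	nsubj	_	_
4	and	and	CCONJ	_	_	3	cc	_	_
5	Bmh2p	bmh2p	PROPN	_	_	3	conj:and	_	_
6	associate	associate	VERB	_	_	0	root	_	_
7	with	with	ADP	_	_	8	case	_	_
8	Ste20p	ste20p	PROPN	_	_	6	nmod:with	_	_
9	in	in	ADP	_	_	10	case	_	_
10	vivo	vivo	X	_	_	6	nmod:in	_	_
11	.	.	PUNCT	_	_	6	punct	_	_

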