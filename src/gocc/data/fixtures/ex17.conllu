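# sent_id = ex17.s1
# text = Hsp70 interacts stably with Hsp40.
1	Hsp70	hsp70	PROPN	_	_	2	nsubj	_	_
2	interacts	interact	VERB	_	_	0	root	_	_
3	stably	stably	ADV	_	_	2	advmod	_	_
4	with	with	ADP	_	_	5	case	_	_
5	Hsp40	hsp40	PROPN	_	_	2	nmod:with	_	_
6	.	.	PUNCT	_	_	2	punct	_	_

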