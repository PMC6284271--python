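# sent_id = ex2.s1
# text = Mad1 dimerizes with Max.
1	Mad1	mad1	PROPN	_	_	2	nsubj	_	_
2	dimerizes	dimerize	VERB	_	_	0	root	_	_
3	with	with	ADP	_	_	4	case	_	_
4	Max	max	PROPN	_	_	2	nmod:with	_	_
5	.	.	PUNCT	_	_	2	punct	_	_

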