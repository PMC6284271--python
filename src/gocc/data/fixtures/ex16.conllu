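# sent_id = ex16.s1
# text = Survivin complexes with Borealin in vivo.
1	Survivin	survivin	PROPN	_	_	2	nsubj	_	_
2	complexes	complex	VERB	_	_	0	root	_	_
3	with	with	ADP	_	_	4	case	_	_
4	Borealin	borealin	PROPN	_	_	2	nmod:with	_	_
5	in	in	ADP	_	_	6	case	_	_
6	vivo	vivo	X	_	_	2	nmod:in	_	_
7	.	.	PUNCT	_	_	2	punct	_	_

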