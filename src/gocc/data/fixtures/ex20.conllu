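# sent_id = ex20.s1
# text = CAR-1 physically interacts with a conserved protein complex.
1	CAR-1	car-1	PROPN	_	_	3	nsubj	_	_
2	physically	physically	ADV	_	_	3	advmod	_	_
3	interacts	interact	VERB	_	_	0	root	_	_
4	with	with	ADP	_	_	8	case	_	_
5	a	a	DET	_	_	8	det	_	_
6	conserved	conserved	ADJ	_	_	8	amod	_	_
7	protein	protein	NOUN	_	_	8	compound	_	_
8	complex	complex	NOUN	_	_	3	nmod:with	_	_
9	.	.	PUNCT	_	_	3	punct	_	_

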