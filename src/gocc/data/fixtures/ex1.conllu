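# sent_id = ex1.s1
# text = CSC-1 is a subunit of the Aurora B kinase complex.
1	CSC-1	csc-1	PROPN	_	_	4	nsubj	_	_
2	is	be	AUX	_	_	4	cop	_	_
3	a	a	DET	_	_	4	det	_	_
4	subunit	subunit	NOUN	_	_	0	root	_	_
5	of	of	ADP	_	_	10	case	_	_
6	the	the	DET	_	_	10	det	_	_
7	Aurora	aurora	PROPN	_	_	10	compound	_	_
8	B	b	PROPN	_	_	10	compound	_	_
9	kinase	kinase	NOUN	_	_	10	compound	_	_
10	complex	complex	NOUN	_	_	4	nmod:of	_	_
11	.	.	PUNCT	_	_	4	punct	_	_

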