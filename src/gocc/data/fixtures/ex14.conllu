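# sent_id = ex14.s1
# text = JAB1 is a subunit of a protein complex.
1	JAB1	jab1	PROPN	_	_	4	nsubj	_	_
2	is	be	AUX	_	_	4	cop	_	_
3	a	a	DET	_	_	4	det	_	_
4	subunit	subunit	NOUN	_	_	0	root	_	_
5	of	of	ADP	_	_	8	case	_	_
6	a	a	DET	_	_	8	det	_	_
7	protein	protein	NOUN	_	_	8	compound	_	_
8	complex	complex	NOUN	_	_	4	nmod:of	_	_
9	.	.	PUNCT	_	_	4	punct	_	_

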