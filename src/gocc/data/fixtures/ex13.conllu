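# sent_id = ex13.s1
# text = Cdc31 was detected in the Sfi1 complex.
1	Cdc31	cdc31	PROPN	_	_	3	nsubjpass	_	_
2	was	be	AUX	_	_	3	auxpass	_	_
3	detected	detect	VERB	_	_	0	root	_	_
4	in	in	ADP	_	_	7	case	_	_
5	the	the	DET	_	_	7	det	_	_
6	Sfi1	sfi1	PROPN	_	_	7	compound	_	_
7	complex	complex	NOUN	_	_	3	nmod:in	_	_
8	.	.	PUNCT	_	_	3	punct	_	_

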