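# sent_id = ex5.s1
# text = ZmHK1 is present in the endoplasmic reticulum.
1	ZmHK1	zmhk1	PROPN	_	_	3	nsubj	_	_
2	is	be	AUX	_	_	3	cop	_	_
3	present	present	ADJ	_	_	0	root	_	_
4	in	in	ADP	_	_	7	case	_	_
5	the	the	DET	_	_	7	det	_	_
6	endoplasmic	endoplasmic	ADJ	_	_	7	amod	_	_
7	reticulum	reticulum	NOUN	_	_	3	nmod:in	_	_
8	.	.	PUNCT	_	_	3	punct	_	_

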