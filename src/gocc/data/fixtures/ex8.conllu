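# sent_id = ex8.s1
# text = SGLT1 is expressed in the plasma membrane.
1	SGLT1	sglt1	PROPN	_	_	3	nsubjpass	_	_
2	is	be	AUX	_	_	3	auxpass	_	_
3	expressed	express	VERB	_	_	0	root	_	_
4	in	in	ADP	_	_	7	case	_	_
5	the	the	DET	_	_	7	det	_	_
6	plasma	plasma	NOUN	_	_	7	compound	_	_
7	membrane	membrane	NOUN	_	_	3	nmod:in	_	_
8	.	.	PUNCT	_	_	3	punct	_	_

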