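# sent_id = ex6.s1
# text = GLUT4 translocates from the cytoplasm to the plasma membrane.
1	GLUT4	glut4	PROPN	_	_	2	nsubj	_	_
2	translocates	translocate	VERB	_	_	0	root	_	_
3	from	from	ADP	_	_	5	case	_	_
4	the	the	DET	_	_	5	det	_	_
5	cytoplasm	cytoplasm	NOUN	_	_	2	nmod:from	_	_
6	to	to	ADP	_	_	9	case	_	_
7	the	the	DET	_	_	9	det	_	_
8	plasma	plasma	NOUN	_	_	9	compound	_	_
9	membrane	membrane	NOUN	_	_	2	nmod:to	_	_
10	.	.	PUNCT	_	_	2	punct	_	_

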