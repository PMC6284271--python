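# sent_id = ex12.s1
# text = The SAGA complex consists of Gcn5 and Ada2.
1	The	the	DET	_	_	3	det	_	_
2	SAGA	saga	PROPN	_	_	3	compound	_	_
3	complex	complex	NOUN	_	_	4	nsubj	_	_
4	consists	consist	VERB	_	_	0	root	_	_
5	of	of	ADP	_	_	6	case	_	_
6	Gcn5	gcn5	PROPN	_	_	4	nmod:of	_	_
7	and	and	CCONJ	_	_	6	cc	_	_
8	Ada2	ada2	PROPN	_	_	6	conj:and	_	_
9	.	.	PUNCT	_	_	4	punct	_	_

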