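# sent_id = staining.s1
# text = The localization of CeCDC-14 was analyzed in wild-type embryos.
1	The	the	DET	_	_	2	det	_	_
2	localization	localization	NOUN	_	_	6	nsubjpass	_	_
3	of	of	ADP	_	_	4	case	_	_
4	CeCDC-14	cecdc-14	PROPN	_	_	2	nmod:of	_	_
5	was	be	AUX	_	_	6	auxpass	_	_
6	analyzed	analyze	VERB	_	_	0	root	_	_
7	in	in	ADP	_	_	9	case	_	_
8	wild-type	wild-type	ADJ	_	_	9	amod	_	_
9	embryos	embryo	NOUN	_	_	6	nmod:in	_	_
10	.	.	PUNCT	_	_	6	punct	_	_

# sent_id = staining.s2
# text = Later in mitosis, this staining compacted to a single dot near the midbody.
1	Later	later	ADV	_	_	7	advmod	_	_
2	in	in	ADP	_	_	3	case	_	_
3	mitosis	mitosis	NOUN	_	_	1	nmod:in	_	_
4	,	,	PUNCT	_	_	7	punct	_	_
5	this	this	DET	_	_	6	det	_	_
6	staining	staining	NOUN	_	_	7	nsubj	_	_
7	compacted	compact	VERB	_	_	0	root	_	_
8	to	to	ADP	_	_	11	case	_	_
9	a	a	DET	_	_	11	det	_	_
10	single	single	ADJ	_	_	11	amod	_	_
11	dot	dot	NOUN	_	_	7	nmod:to	_	_
12	near	near	ADP	_	_	14	case	_	_
13	the	the	DET	_	_	14	det	_	_
14	midbody	midbody	NOUN	_	_	11	nmod:near	_	_
15	.	.	PUNCT	_	_	7	punct	_	_

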