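# sent_id = ex5n.s1
# text = The detection of ZmHK1 in the endoplasmic reticulum was reported.
1	The	the	DET	_	_	2	det	_	_
2	detection	detection	NOUN	_	_	10	nsubjpass	_	_
3	of	of	ADP	_	_	4	case	_	_
4	ZmHK1	zmhk1	PROPN	_	_	2	nmod:of	_	_
5	in	in	ADP	_	_	8	case	_	_
6	the	the	DET	_	_	8	det	_	_
7	endoplasmic	endoplasmic	ADJ	_	_	8	amod	_	_
8	reticulum	reticulum	NOUN	_	_	2	nmod:in	_	_
9	was	be	AUX	_	_	10	auxpass	_	_
10	reported	report	VERB	_	_	0	root	_	_
11	.	.	PUNCT	_	_	10	punct	_	_

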