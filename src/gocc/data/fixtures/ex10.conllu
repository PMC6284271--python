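# sent_id = ex10.s1
# text = MRE complex contains Sp1 or related proteins.
1	MRE	mre	PROPN	_	_	2	compound	_	_
2	complex	complex	NOUN	_	_	3	nsubj	_	_
3	contains	contain	VERB	_	_	0	root	_	_
4	Sp1	sp1	PROPN	_	_	3	dobj	_	_
5	or	or	CCONJ	_	_	4	cc	_	_
6	related	related	ADJ	_	_	7	amod	_	_
7	proteins	protein	NOUN	_	_	4	conj:or	_	_
8	.	.	PUNCT	_	_	3	punct	_	_

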