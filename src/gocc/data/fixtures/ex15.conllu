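# sent_id = ex15.s1
# text = Ku70 and Ku80 form a tight heterodimer.
1	Ku70	ku70	PROPN	_	_	4	nsubj	_	_
2	and	and	CCONJ	_	_	1	cc	_	_
3	Ku80	ku80	PROPN	_	_	1	conj:and	_	_
4	form	form	VERB	_	_	0	root	_	_
5	a	a	DET	_	_	7	det	_	_
6	tight	tight	ADJ	_	_	7	amod	_	_
7	heterodimer	heterodimer	NOUN	_	_	4	dobj	_	_
8	.	.	PUNCT	_	_	4	punct	_	_

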