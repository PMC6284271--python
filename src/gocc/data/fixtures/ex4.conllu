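# sent_id = ex4.s1
# text = SIRT2 is found primarily in the cytoplasm.
1	SIRT2	sirt2	PROPN	_	_	3	nsubjpass	_	_
2	is	be	AUX	_	_	3	auxpass	_	_
3	found	find	VERB	_	_	0	root	_	_
4	primarily	primarily	ADV	_	_	3	advmod	_	_
5	in	in	ADP	_	_	7	case	_	_
6	the	the	DET	_	_	7	det	_	_
7	cytoplasm	cytoplasm	NOUN	_	_	3	nmod:in	_	_
8	.	.	PUNCT	_	_	3	punct	_	_

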