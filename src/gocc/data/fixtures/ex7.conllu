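# sent_id = ex7.s1
# text = Fbxo45 interacts with Par-4 in the cytoplasm.
1	Fbxo45	fbxo45	PROPN	_	_	2	nsubj	_	_
2	interacts	interact	VERB	_	_	0	root	_	_
3	with	with	ADP	_	_	4	case	_	_
4	Par-4	par-4	PROPN	_	_	2	nmod:with	_	_
5	in	in	ADP	_	_	7	case	_	_
6	the	the	DET	_	_	7	det	_	_
7	cytoplasm	cytoplasm	NOUN	_	_	2	nmod:in	_	_
8	.	.	PUNCT	_	_	2	punct	_	_

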