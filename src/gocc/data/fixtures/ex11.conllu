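# sent_id = ex11.s1
# text = Rpn10 is a component of the 26S proteasome.
1	Rpn10	rpn10	PROPN	_	_	4	nsubj	_	_
2	is	be	AUX	_	_	4	cop	_	_
3	a	a	DET	_	_	4	det	_	_
4	component	component	NOUN	_	_	0	root	_	_
5	of	of	ADP	_	_	8	case	_	_
6	the	the	DET	_	_	8	det	_	_
7	26S	26s	PROPN	_	_	8	compound	_	_
8	proteasome	proteasome	NOUN	_	_	4	nmod:of	_	_
9	.	.	PUNCT	_	_	4	punct	_	_

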