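# sent_id = cd3.s1
# text = The cytoplasmic CD3 levels increased.
1	The	the	DET	_	_	4	det	_	_
2	cytoplasmic	cytoplasmic	ADJ	_	_	4	amod	_	_
3	CD3	cd3	PROPN	_	_	4	compound	_	_
4	levels	level	NOUN	_	_	5	nsubj	_	_
5	increased	increase	VERB	_	_	0	root	_	_
6	.	.	PUNCT	_	_	5	punct	_	_

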