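# sent_id = ex3.s1
# text = The yeast eIF3 complex contains five core components: Rpg1, Nip1, Prt1, Tif34, and Tif35.
1	The	the	DET	_	_	4	det	_	_
2	yeast	yeast	NOUN	_	_	4	compound	_	_
3	eIF3	eif3	PROPN	_	_	4	compound	_	_
4	complex	complex	NOUN	_	_	5	nsubj	_	_
5	contains	contain	VERB	_	_	0	root	_	_
6	five	five	NUM	_	_	8	nummod	_	_
7	core	core	NOUN	_	_	8	compound	_	_
8	components	component	NOUN	_	_	5	dobj	_	_
9	:	:	PUNCT	_	_	8	punct	_	_
10	Rpg1	rpg1	PROPN	_	_	8	appos	_	_
11	,	,	PUNCT	_	_	10	punct	_	_
12	Nip1	nip1	PROPN	_	_	10	conj:and	_	_
13	,	,	PUNCT	_	_	10	punct	_	_
14	Prt1	prt1	PROPN	_	_	10	conj:and	_	_
15	,	,	PUNCT	_	_	10	punct	_	_
16	Tif34	tif34	PROPN	_	_	10	conj:and	_	_
17	,	,	PUNCT	_	_	10	punct	_	_
18	and	and	CCONJ	_	_	10	cc	_	_
19	Tif35	tif35	PROPN	_	_	10	conj:and	_	_
20	.	.	PUNCT	_	_	5	punct	_	_

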