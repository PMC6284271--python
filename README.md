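# gocc — gene annotation with GO Cellular Component terms

`gocc` annotates genes mentioned in biomedical text with Gene Ontology
**Cellular Component (CC)** terms, for curators and text-mining pipelines
that need literature-scale GO annotation support. Instead of treating GO
annotation as term retrieval, it casts the CC domain as two
relation-extraction tasks over dependency parses:

1. **protein found-in subcellular location** — "SIRT2 is found primarily in
   the cytoplasm" ⇒ (SIRT2, `GO:0005737` cytoplasm);
2. **protein is a component of a protein complex** — "CSC-1 is a subunit of
   the Aurora B kinase complex" ⇒ (CSC-1, `GO:0043234` protein complex).

## Method

A *trigger* is a word whose presence, together with satisfied dependency
constraints, signals a relation. Given a sentence graph with UD-style
labels and Stanford-style preposition collapsing (`nsubj`, `dobj`,
`nmod:in`, `conj:and`, ...), the rule engine:

- matches trigger lemmas in ten configurable classes (found-in, movement,
  event, part-whole noun, containment verb, detected-in, formation, PPI,
  stability marker, staining), in verbal, nominal and adjectival form;
- checks the trigger's arguments: e.g. found-in needs a protein subject
  and a *locative* prepositional modifier (`nmod:in/at/on`), movement verbs
  select directional prepositions (`nmod:to/from`) instead;
- propagates through extra-syntactic structure: member-collection
  enumerations ("contains five core components: Rpg1, Nip1, ...") expand a
  relation on the collection noun to every member, and copular predicates
  resolve to their subjects;
- promotes a plain protein–protein interaction to complex co-membership
  only when the text shows it is **stable**, **performs a function** (the
  PPI trigger is conjoined to another verb), or involves **more than two
  components**;
- maps mentions to GO: locations through a dictionary built from the 19
  subcellular-location root terms of the CC hierarchy, complexes through a
  PRO/Complex Portal/CORUM-style name map, with `GO:0043234` ("protein
  complex") as the fallback; f-term phrases (head nouns matching
  `/(complex|dimer|trimer|...)$/`) let generic mentions like "a protein
  complex" count as valid context.

Document-level output is a deduplicated set of (doc, gene, GO-ID) triplets
with a full audit trail of the rules that fired, restricted to
abstract/results/discussion/conclusion sections. The `evaluation` module
scores triplets against a gold standard (BioC XML) with precision
P = TP/(TP+FP), recall R = TP/(TP+FN) and F1 = 2PR/(P+R).

Protein mention detection and gene normalization are upstream concerns:
normalized mentions enter as stand-off rows `(sent_id, start, end,
gene_id)`. Parsing is likewise pluggable — all shipped fixtures are gold
CoNLL-U parses.

## Worked example

```python
from gocc.fixtures import load_fixture, run_case

case = load_fixture("ex3")
relations, annotations = run_case(case)
for a in annotations:
    print(a.gene_id, a.go_id)
```

prints

```
GID:Nip1 GO:0005852
GID:Prt1 GO:0005852
GID:Rpg1 GO:0005852
GID:Tif34 GO:0005852
GID:Tif35 GO:0005852
```

one triplet per enumerated component of the eIF3 complex: the containment
rule fires on "contains", member-collection expansion distributes the
relation over the five listed proteins, and the complex-name dictionary
links "eIF3 complex" to its specific GO entry `GO:0005852`. The
`examples/` directory has one short script per capability (sentence-level
extraction, corpus annotation, evaluation, synthetic stress suite), and a
thin CLI does the same from the shell:

```bash
gocc annotate --conllu parses.conllu --entities mentions.tsv --out triplets.tsv
```

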