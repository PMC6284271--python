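# Methods

## Task and model

The package treats Gene Ontology Cellular Component annotation as relation
extraction. The CC domain splits into two sub-hierarchies: subcellular
locations (all terms reachable from 19 root terms that sit directly under
`cellular_component`) and protein complexes (the sub-hierarchy under
`GO:0043234`). Correspondingly, two families of sentence-level relations
are extracted and then aggregated to document-level (doc, gene, GO-ID)
triplets.

The extraction model is trigger + dependency constraints. Each rule names
a trigger class, the syntactic form it accepts (verbal, nominal,
adjectival) and the labeled dependency paths its arguments must occupy.
Rules read the parse and record their output as separate argument edges
(`argComponent`, `argComplex`, `argLocation`), never mutating the parse;
this keeps rule interaction transparent and the firing trace auditable.

Assumptions worth stating explicitly:

- **Sentence scope.** All rules except the staining heuristic operate
  within one sentence. Anaphora ("both proteins", "it") and
  multi-sentence evidence are out of scope; on real text these are the
  dominant source of misses.
- **Findings, not knowledge.** Adjectival location premodifiers of a
  protein ("cytoplasmic CD3") are treated as background knowledge and
  deliberately excluded; only predications count as annotation evidence.
- **Species independence.** GO terms are not species-specific, so complex
  dictionary lookup ignores species.

## Dependency dialect

Rules match UD-style labels with Stanford-style preposition collapsing:
one edge `nmod:<prep>` per prepositional modifier and `conj:<cc>` where
the coordinator is recoverable. The CoNLL-U reader normalizes plain UD
(`nmod`/`obl` plus `case`; `conj` plus `cc`) into this form, so gold
fixtures and modern parser output look identical to the rules.
Normalization is a pure function of the parse: two serializations of the
same structure yield the same graph. Live parsing sits behind a small
adapter protocol (text → sentence graphs); nothing in the package needs a
parser at test time.

Only labels evidenced by the rule inventory are interpreted (`nsubj`,
`nsubjpass`, `dobj`, `nmod:<prep>`, `conj`, `appos`, `cop`, `amod`,
`advmod`, `xcomp`/`advcl`, `compound`, `case`, `cc`); the accepted subject
and object variants are small tuples in `depgraph` so passive/UD-v2
spellings (`nsubj:pass`, `obj`) can be extended without touching rules.

## Rule families and their parameters

- **found-in** (high confidence): locative prepositions default to
  `{in, at, on, within, inside}`. Nominal triggers take their protein via
  `nmod:of` or a nominal compound; adjectival triggers resolve through the
  copula.
- **movement** (high): directional prepositions `{to, from, into,
  toward(s)}`. The moved entity is the object for transitives/passives,
  else the subject. Plain locative `in` is rejected by default
  (`accept_locative_in=True` opts in) because movement verbs select goals
  and sources, not static locations.
- **event-in-location** (high): any event-class trigger carrying a
  locative modifier places *all* of its protein arguments
  (`nsubj`/`dobj`/`nmod:with`, member-collection expanded) in the
  location. The event class is deliberately broad and fully
  config-driven.
- **staining** (low confidence): a staining trigger, at least one location
  in the same sentence, and *exactly one* distinct non-tag protein in the
  same or immediately preceding sentence. The window is never wider; tag
  names (GFP, FLAG, ...) never anchor the inference.
- **part-whole** (high): three argument configurations — predicate
  nominal ("P is a subunit of C"), containment verb ("C contains P",
  "C consists of P"), passive detection ("P was detected in C").
- **formation** (high): "form"-type verb with an f-term object; verbs
  whose lemma is itself an f-term base ("dimerizes with", "complexes
  with", recognized by stripping `-ize`/`-ise`); nominal triggers
  ("dimerization of A and B").
- **PPI + promotion**: interactions are extracted per unordered protein
  pair, then promoted to `component_component` only on (a) a stability
  marker modifying the trigger or its object, (b) function evidence — a
  conjoined verb, or an `xcomp`/`advcl` purpose clause (the conjunction
  case is the documented one; the purpose clause is this package's
  conservative generalization) — or (c) more than two participants.

### Unnamed participants

Components need not be named proteins. Unnamed nominal arguments
("... with several other proteins") count toward the more-than-two
threshold, and a complex-phrase partner ("interacts with a conserved
protein complex") is counted as two components, since a complex has at
least two — so a single named protein interacting with a complex clears
the threshold and receives a `part_of_complex` relation. Only named,
normalized proteins ever receive annotations. To let this context survive
into promotion, a PPI relation may carry roles protein + complex instead
of two proteins; it is the one relaxation of the otherwise strict
role-per-type invariants.

## Dictionaries and lexicons

- **Location dictionary**: names (and, by default, exact synonyms) of all
  terms reachable from the 19 roots via `is_a` and `part_of`; `part_of`
  is included by default because the CC hierarchy is part_of-heavy, and an
  `is_a`-only mode exists. Matching is case-insensitive, token-aligned,
  contiguous, leftmost-longest, with a lemma fallback so plurals match.
  The head of a match is its last token (English nominals are
  right-headed).
- **Complex dictionary**: TSV name → GO map in the style of PRO / Complex
  Portal / CORUM exports; a known name with a blank GO link still tags a
  `complex_name` mention and falls back to `GO:0043234` at mapping time.
- **f-terms**: the suffix alternation
  `(complex|dimer|trimer|tramer|hexamer|nonamer|tamer|decamer|octomer|oligomer)$`
  is matched verbatim. Note the suffixes cover more than they literally
  spell — "tetramer" ends in `tramer`, "pentamer" and "octamer" end in
  `tamer` — so the `extended=True` variant (which adds those three
  spellings explicitly) is behaviorally identical on them and exists only
  for clarity.
- **Trigger lexicon**: ten classes in a YAML config; the packaged default
  is seeded from the vocabulary the rules were designed around and is
  intentionally non-exhaustive. Matching is by lemma or lowercased
  surface, so inflected forms can be listed where lemmatizers disagree.

## Section filter and assembly

Predictions are restricted to abstract/results/discussion/conclusion
passages, by keyword membership of the normalized section label (so
"Results and Discussion" is retained). A document with no recognizable
labels is kept whole with a warning; a strict mode drops it instead.
Triplets are deduplicated per document with evidence concatenated and
ordered deterministically by (doc, gene, GO-ID). Low-confidence staining
triplets are included by default (they contribute recall) and excluded by
`high_confidence_only`.

## Evaluation

Triplet comparison is exact-match; precision is undefined (reported 0,
flagged) for empty prediction sets, recall likewise for empty gold sets.
An ancestor-credit mode was considered and rejected for the default:
hierarchy-aware matching changes the metric's meaning and the exact
convention is the defensible baseline. The CC-domain filter for gold sets
is membership in the closure of the 19 location roots plus the complex
sub-hierarchy. BioC infon keys vary across corpus releases, so the gene
and GO keys are arguments with permissive defaults, not constants.

## Fixtures and the synthetic generator

The shipped fixtures are gold parses of the worked example sentences the
method is built around. Sentences that are only described structurally in
the source material are reconstructed as surrogates exhibiting the same
dependency pattern and flagged `surrogate=True`; their exact wording is
this package's choice, their structure is not. Expected outputs were
written by hand from the described behavior before being run.

The synthetic generator builds sentence graphs directly from templates —
one per rule family, plus distractors that must yield nothing (movement
trigger with a locative preposition, non-locative modifier, two-candidate
staining windows, adjectival location premodifiers). Each template records
its expected relations at construction time, independently of the
extraction code. What passing does **not** show: the templates use clean,
single-clause parses with gold protein mentions, so results say nothing
about parser noise, NER errors, long coordination, negation or hedging —
on real corpora those, plus multi-sentence evidence, are the dominant
error sources. Problem sizes are deliberately small (23 worked cases, 100
synthetic cases per run); everything completes in seconds.

## Numerical and degenerate-input choices

No floating-point computation beyond the three evaluation ratios.
Tie-breaks are structural: dictionary matching prefers the longest span
and the leftmost start; dependents are always iterated in token order, so
extraction is deterministic for identical inputs. Degenerate inputs have
defined behavior throughout: empty streams yield empty results, malformed
CoNLL-U and out-of-bounds stand-off spans raise errors naming the line or
row, unknown trigger classes and missing ontology roots raise
configuration errors naming the offender, and conflicting complex-name
mappings are rejected rather than silently last-one-wins.

## Known limitations

Single-sentence scope (except staining); no anaphora; no negation or
hedging handling; contiguous-only dictionary matching; the PPI trigger
inventory is limited to the documented classes rather than a full
interaction-extraction system; gene normalization quality is entirely
upstream. Corpus-scale figures therefore depend on components outside
this package and are not claimed by its tests.
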