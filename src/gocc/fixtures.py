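"""Worked-example fixtures and a synthetic sentence generator.

The package ships hand-annotated dependency parses for the worked example
sentences the method was designed around (``ex1`` ... ``ex20``, plus a
nominal-trigger variant ``ex5n``, an adjectival-knowledge distractor
``cd3`` and a two-sentence ``staining`` passage).  Sentences whose full
text is not on record are reconstructed as faithful *surrogates* of the
described dependency pattern and flagged ``surrogate=True``.

:func:`generate_synthetic` produces seeded template cases — one template
per rule family plus distractor templates that must yield nothing — each
carrying its analytically known expected output, for large-scale
equivalence testing of the extractors.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass
from functools import lru_cache

from .annotate import GOAnnotation, annotate_document
from .depgraph import DepEdge, Document, Passage, SentenceGraph, Token, normalize_edges, read_conllu
from .entities import EntityMention, read_standoff_proteins
from .lexicons import (
    ComplexDictionary,
    LocationDictionary,
    TriggerLexicon,
    build_complex_dictionary,
    build_location_dictionary,
    default_triggers,
    packaged_data,
)
from .location_rules import Relation

__all__ = [
    "FixtureCase",
    "CASE_IDS",
    "load_fixture",
    "load_all_fixtures",
    "run_case",
    "generate_synthetic",
    "build_sentence",
    "fixture_resources",
    "expected_signature",
    "relation_signatures",
]

#: Shipped worked-example cases.  ex1 and ex9 are the same sentence in the
#: source material; both ids are available.
CASE_IDS = (
    "ex1",
    "ex2",
    "ex3",
    "ex4",
    "ex5",
    "ex5n",
    "ex6",
    "ex7",
    "ex8",
    "ex9",
    "ex10",
    "ex11",
    "ex12",
    "ex13",
    "ex14",
    "ex15",
    "ex16",
    "ex17",
    "ex18",
    "ex19",
    "ex20",
    "cd3",
    "staining",
)


@dataclass
class FixtureCase:
    """A test sentence (or passage) with its analytically known output."""

    case_id: str
    document: Document
    proteins: list[EntityMention]
    expected: list[dict]
    expected_triplets: list[tuple[str, str]]
    surrogate: bool = False

    @property
    def sentences(self) -> list[SentenceGraph]:
        return list(self.document.sentences())

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sentences)


# ---------------------------------------------------------------------------
# sentence builder (used by the synthetic templates and the fixture data)

_NO_SPACE_BEFORE = {",", ".", ":", ";", "?", "!", ")"}


def build_sentence(
    sent_id: str,
    rows: list[tuple[str, str, str]],
    edges: list[tuple[int, int, str]],
) -> SentenceGraph:
    """Construct a :class:`SentenceGraph` from ``(form, lemma, pos)`` rows
    and ``(head, dependent, label)`` edges; offsets come from standard
    detokenization (no space before sentence-final punctuation etc.)."""
    text = ""
    tokens: list[Token] = []
    for i, (form, lemma, pos) in enumerate(rows, start=1):
        if text and form not in _NO_SPACE_BEFORE and not text.endswith("("):
            text += " "
        start = len(text)
        text += form
        tokens.append(Token(i, form, lemma, pos, start, len(text)))
    edge_set = {DepEdge(h, d, l) for h, d, l in edges}
    return SentenceGraph(sent_id, text, tuple(tokens), normalize_edges(tokens, edge_set))


def protein_mention(g: SentenceGraph, token_index: int, gene_id: str) -> EntityMention:
    t = g.token(token_index)
    return EntityMention(
        sent_id=g.sent_id,
        char_start=t.char_start,
        char_end=t.char_end,
        head_token=t.index,
        etype="protein",
        text=t.text,
        norm_id=gene_id,
        is_tag=t.text in default_triggers().tags,
    )


# ---------------------------------------------------------------------------
# shipped fixtures


@lru_cache(maxsize=1)
def fixture_resources() -> tuple[LocationDictionary, ComplexDictionary, TriggerLexicon]:
    """Packaged location dictionary, complex dictionary and trigger lexicon."""
    loc = build_location_dictionary(io.StringIO(packaged_data("go_cc_subset_synthetic.obo")))
    cx = build_complex_dictionary(io.StringIO(packaged_data("complexes.tsv")))
    return loc, cx, default_triggers()


@lru_cache(maxsize=1)
def _expected_index() -> dict:
    return json.loads(packaged_data("fixtures/expected.json"))


def load_fixture(case_id: str) -> FixtureCase:
    """Load a shipped worked-example case; unknown ids raise ``KeyError``."""
    if case_id not in CASE_IDS:
        raise KeyError(f"unknown fixture case {case_id!r}")
    sentences = read_conllu(packaged_data(f"fixtures/{case_id}.conllu"))
    doc = Document(case_id, [Passage("results", sentences)])
    proteins = read_standoff_proteins(
        io.StringIO(packaged_data(f"fixtures/{case_id}.mentions.tsv")), doc
    )
    info = _expected_index()[case_id]
    return FixtureCase(
        case_id=case_id,
        document=doc,
        proteins=proteins,
        expected=info["relations"],
        expected_triplets=[tuple(t) for t in info["triplets"]],
        surrogate=info["surrogate"],
    )


def load_all_fixtures() -> list[FixtureCase]:
    return [load_fixture(cid) for cid in CASE_IDS]


def run_case(case: FixtureCase) -> tuple[list[Relation], list[GOAnnotation]]:
    """Run the full pipeline on a case with the packaged resources."""
    loc, cx, lex = fixture_resources()
    return annotate_document(
        case.document, case.proteins, loc, cx, lex, apply_section_filter=False
    )


# ---------------------------------------------------------------------------
# comparison helpers


def expected_signature(d: dict) -> tuple:
    """Signature tuple for an expected-relation dict, comparable with
    :meth:`gocc.location_rules.Relation.signature`."""
    conf = d.get("confidence", "high")
    rtype = d["rtype"]
    skip = ("rtype", "confidence", "pair")
    if "pair" in d:
        rest = tuple(sorted((k, v) for k, v in d.items() if k not in skip))
        return (rtype, tuple(sorted(d["pair"])), rest, conf)
    if rtype in ("component_component", "ppi"):
        pair = tuple(sorted(d[k] for k in ("protein", "protein2") if k in d))
        rest = tuple(
            sorted((k, v) for k, v in d.items() if k not in skip + ("protein", "protein2"))
        )
        return (rtype, pair, rest, conf)
    roles = tuple(sorted((k, v) for k, v in d.items() if k not in skip))
    return (rtype, roles, (), conf)


def relation_signatures(relations: list[Relation]) -> list[tuple]:
    return sorted(r.signature() for r in relations)


def expected_signatures(case: FixtureCase) -> list[tuple]:
    return sorted(expected_signature(d) for d in case.expected)


# ---------------------------------------------------------------------------
# synthetic templates

_PROTEIN_POOL = (
    "Abc1", "Dlk2", "Rfx5", "Pex7", "Smc3", "Vps4", "Nup98", "Rab11",
    "Cdk2", "Apc5", "Gle1", "Sec13", "Tom20", "Hsf1", "Pds5", "Mre11",
)
_LOCATION_POOL = (
    ("cytoplasm", "GO:0005737"),
    ("nucleus", "GO:0005634"),
    ("cytosol", "GO:0005829"),
    ("midbody", "GO:0030496"),
    ("membrane", "GO:0016020"),
    ("mitochondria", "GO:0005739"),
)
_COMPLEX_NAME_POOL = ("Aurora", "SAGA", "NuRD", "TREX", "MCM", "ORC")


def _gid(name: str) -> str:
    return f"GID:{name}"


def _case(case_id, graphs, prot_specs, expected, triplets) -> FixtureCase:
    doc = Document(case_id, [Passage("results", list(graphs))])
    proteins = [protein_mention(g, idx, gid) for g, idx, gid in prot_specs]
    return FixtureCase(case_id, doc, proteins, expected, triplets, surrogate=True)


def _t_found_verbal(rng, cid):
    p = rng.choice(_PROTEIN_POOL)
    loc, go = rng.choice(_LOCATION_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("is", "be", "AUX"), ("found", "find", "VERB"),
         ("mainly", "mainly", "ADV"), ("in", "in", "ADP"), ("the", "the", "DET"),
         (loc, loc, "NOUN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 4, "advmod"),
         (3, 7, "nmod:in"), (7, 5, "case"), (7, 6, "det"), (3, 8, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p))],
                 [{"rtype": "found_in", "protein": p, "location": loc}],
                 [(_gid(p), go)])


def _t_found_nominal(rng, cid):
    p = rng.choice(_PROTEIN_POOL)
    loc, go = rng.choice(_LOCATION_POOL)
    g = build_sentence(
        cid + ".s1",
        [("The", "the", "DET"), ("detection", "detection", "NOUN"), ("of", "of", "ADP"),
         (p, p.lower(), "PROPN"), ("in", "in", "ADP"), ("the", "the", "DET"),
         (loc, loc, "NOUN"), ("was", "be", "AUX"), ("unexpected", "unexpected", "ADJ"),
         (".", ".", "PUNCT")],
        [(2, 1, "det"), (2, 4, "nmod:of"), (4, 3, "case"), (2, 7, "nmod:in"),
         (7, 5, "case"), (7, 6, "det"), (9, 2, "nsubj"), (9, 8, "cop"), (9, 10, "punct")],
    )
    return _case(cid, [g], [(g, 4, _gid(p))],
                 [{"rtype": "found_in", "protein": p, "location": loc}],
                 [(_gid(p), go)])


def _t_found_adjectival(rng, cid):
    p = rng.choice(_PROTEIN_POOL)
    loc, go = rng.choice(_LOCATION_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("is", "be", "AUX"), ("present", "present", "ADJ"),
         ("in", "in", "ADP"), ("the", "the", "DET"), (loc, loc, "NOUN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubj"), (3, 2, "cop"), (3, 6, "nmod:in"), (6, 4, "case"),
         (6, 5, "det"), (3, 7, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p))],
                 [{"rtype": "found_in", "protein": p, "location": loc}],
                 [(_gid(p), go)])


def _t_movement_active(rng, cid):
    p = rng.choice(_PROTEIN_POOL)
    loc, go = rng.choice(_LOCATION_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("translocates", "translocate", "VERB"),
         ("to", "to", "ADP"), ("the", "the", "DET"), (loc, loc, "NOUN"), (".", ".", "PUNCT")],
        [(2, 1, "nsubj"), (2, 5, "nmod:to"), (5, 3, "case"), (5, 4, "det"), (2, 6, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p))],
                 [{"rtype": "moves", "protein": p, "location": loc}],
                 [(_gid(p), go)])


def _t_movement_passive(rng, cid):
    p = rng.choice(_PROTEIN_POOL)
    loc, go = rng.choice(_LOCATION_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("was", "be", "AUX"), ("recruited", "recruit", "VERB"),
         ("to", "to", "ADP"), ("the", "the", "DET"), (loc, loc, "NOUN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 6, "nmod:to"), (6, 4, "case"),
         (6, 5, "det"), (3, 7, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p))],
                 [{"rtype": "moves", "protein": p, "location": loc}],
                 [(_gid(p), go)])


def _t_movement_distractor(rng, cid):
    # movement trigger with a plain locative preposition: must yield nothing
    p = rng.choice(_PROTEIN_POOL)
    loc, _go = rng.choice(_LOCATION_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("was", "be", "AUX"), ("recruited", "recruit", "VERB"),
         ("in", "in", "ADP"), ("the", "the", "DET"), (loc, loc, "NOUN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 6, "nmod:in"), (6, 4, "case"),
         (6, 5, "det"), (3, 7, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p))], [], [])


def _t_event_pair(rng, cid):
    p, q = rng.sample(_PROTEIN_POOL, 2)
    loc, go = rng.choice(_LOCATION_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("interacts", "interact", "VERB"), ("with", "with", "ADP"),
         (q, q.lower(), "PROPN"), ("in", "in", "ADP"), ("the", "the", "DET"),
         (loc, loc, "NOUN"), (".", ".", "PUNCT")],
        [(2, 1, "nsubj"), (2, 4, "nmod:with"), (4, 3, "case"), (2, 7, "nmod:in"),
         (7, 5, "case"), (7, 6, "det"), (2, 8, "punct")],
    )
    return _case(
        cid, [g], [(g, 1, _gid(p)), (g, 4, _gid(q))],
        [{"rtype": "event_in", "protein": p, "location": loc},
         {"rtype": "event_in", "protein": q, "location": loc},
         {"rtype": "ppi", "pair": [p, q]}],
        [(_gid(p), go), (_gid(q), go)],
    )


def _t_event_passive(rng, cid):
    p = rng.choice(_PROTEIN_POOL)
    loc, go = rng.choice(_LOCATION_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("is", "be", "AUX"), ("expressed", "express", "VERB"),
         ("in", "in", "ADP"), ("the", "the", "DET"), (loc, loc, "NOUN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 6, "nmod:in"), (6, 4, "case"),
         (6, 5, "det"), (3, 7, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p))],
                 [{"rtype": "event_in", "protein": p, "location": loc}],
                 [(_gid(p), go)])


def _t_partwhole_type1(rng, cid):
    p = rng.choice(_PROTEIN_POOL)
    c = rng.choice(_COMPLEX_NAME_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("is", "be", "AUX"), ("a", "a", "DET"),
         ("subunit", "subunit", "NOUN"), ("of", "of", "ADP"), ("the", "the", "DET"),
         (c, c.lower(), "PROPN"), ("complex", "complex", "NOUN"), (".", ".", "PUNCT")],
        [(4, 1, "nsubj"), (4, 2, "cop"), (4, 3, "det"), (4, 8, "nmod:of"),
         (8, 5, "case"), (8, 6, "det"), (8, 7, "compound"), (4, 9, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p))],
                 [{"rtype": "part_of_complex", "protein": p, "complex": f"{c} complex"}],
                 [(_gid(p), "GO:0043234")])


def _t_partwhole_type2(rng, cid):
    c = rng.choice(_COMPLEX_NAME_POOL)
    p, q, r = rng.sample(_PROTEIN_POOL, 3)
    g = build_sentence(
        cid + ".s1",
        [("The", "the", "DET"), (c, c.lower(), "PROPN"), ("complex", "complex", "NOUN"),
         ("contains", "contain", "VERB"), ("three", "three", "NUM"),
         ("subunits", "subunit", "NOUN"), (":", ":", "PUNCT"),
         (p, p.lower(), "PROPN"), (",", ",", "PUNCT"), (q, q.lower(), "PROPN"),
         (",", ",", "PUNCT"), ("and", "and", "CCONJ"), (r, r.lower(), "PROPN"),
         (".", ".", "PUNCT")],
        [(3, 1, "det"), (3, 2, "compound"), (4, 3, "nsubj"), (4, 6, "dobj"),
         (6, 5, "nummod"), (6, 7, "punct"), (6, 8, "appos"), (8, 9, "punct"),
         (8, 10, "conj:and"), (8, 11, "punct"), (8, 12, "cc"), (8, 13, "conj:and"),
         (4, 14, "punct")],
    )
    cx = f"{c} complex"
    return _case(
        cid, [g], [(g, 8, _gid(p)), (g, 10, _gid(q)), (g, 13, _gid(r))],
        [{"rtype": "part_of_complex", "protein": x, "complex": cx} for x in (p, q, r)],
        [(_gid(x), "GO:0043234") for x in (p, q, r)],
    )


def _t_partwhole_type3(rng, cid):
    p = rng.choice(_PROTEIN_POOL)
    c = rng.choice(_COMPLEX_NAME_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("was", "be", "AUX"), ("detected", "detect", "VERB"),
         ("in", "in", "ADP"), ("the", "the", "DET"), (c, c.lower(), "PROPN"),
         ("complex", "complex", "NOUN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 7, "nmod:in"), (7, 4, "case"),
         (7, 5, "det"), (7, 6, "compound"), (3, 8, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p))],
                 [{"rtype": "part_of_complex", "protein": p, "complex": f"{c} complex"}],
                 [(_gid(p), "GO:0043234")])


def _t_formation_form(rng, cid):
    p, q, r = rng.sample(_PROTEIN_POOL, 3)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), (",", ",", "PUNCT"), (q, q.lower(), "PROPN"),
         ("and", "and", "CCONJ"), (r, r.lower(), "PROPN"), ("form", "form", "VERB"),
         ("a", "a", "DET"), ("stable", "stable", "ADJ"), ("trimer", "trimer", "NOUN"),
         (".", ".", "PUNCT")],
        [(6, 1, "nsubj"), (1, 2, "punct"), (1, 3, "conj:and"), (1, 4, "cc"),
         (1, 5, "conj:and"), (6, 9, "dobj"), (9, 7, "det"), (9, 8, "amod"),
         (6, 10, "punct")],
    )
    cx = "stable trimer"
    pairs = [[p, q], [p, r], [q, r]]
    return _case(
        cid, [g], [(g, 1, _gid(p)), (g, 3, _gid(q)), (g, 5, _gid(r))],
        [{"rtype": "component_component", "pair": pr} for pr in pairs]
        + [{"rtype": "part_of_complex", "protein": x, "complex": cx} for x in (p, q, r)],
        [(_gid(x), "GO:0043234") for x in (p, q, r)],
    )


def _t_formation_verb(rng, cid):
    p, q = rng.sample(_PROTEIN_POOL, 2)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("dimerizes", "dimerize", "VERB"), ("with", "with", "ADP"),
         (q, q.lower(), "PROPN"), (".", ".", "PUNCT")],
        [(2, 1, "nsubj"), (2, 4, "nmod:with"), (4, 3, "case"), (2, 5, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p)), (g, 4, _gid(q))],
                 [{"rtype": "component_component", "pair": [p, q]}],
                 [(_gid(p), "GO:0043234"), (_gid(q), "GO:0043234")])


def _t_formation_nominal(rng, cid):
    p, q = rng.sample(_PROTEIN_POOL, 2)
    g = build_sentence(
        cid + ".s1",
        [("Dimerization", "dimerization", "NOUN"), ("of", "of", "ADP"),
         (p, p.lower(), "PROPN"), ("and", "and", "CCONJ"), (q, q.lower(), "PROPN"),
         ("occurs", "occur", "VERB"), ("rapidly", "rapidly", "ADV"), (".", ".", "PUNCT")],
        [(1, 3, "nmod:of"), (3, 2, "case"), (3, 5, "conj:and"), (3, 4, "cc"),
         (6, 1, "nsubj"), (6, 7, "advmod"), (6, 8, "punct")],
    )
    return _case(cid, [g], [(g, 3, _gid(p)), (g, 5, _gid(q))],
                 [{"rtype": "component_component", "pair": [p, q]}],
                 [(_gid(p), "GO:0043234"), (_gid(q), "GO:0043234")])


def _t_ppi_stable(rng, cid):
    p, q = rng.sample(_PROTEIN_POOL, 2)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("stably", "stably", "ADV"),
         ("associates", "associate", "VERB"), ("with", "with", "ADP"),
         (q, q.lower(), "PROPN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubj"), (3, 2, "advmod"), (3, 5, "nmod:with"), (5, 4, "case"),
         (3, 6, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p)), (g, 5, _gid(q))],
                 [{"rtype": "ppi", "pair": [p, q]},
                  {"rtype": "component_component", "pair": [p, q]}],
                 [(_gid(p), "GO:0043234"), (_gid(q), "GO:0043234")])


def _t_ppi_function(rng, cid):
    p, q = rng.sample(_PROTEIN_POOL, 2)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("binds", "bind", "VERB"), (q, q.lower(), "PROPN"),
         ("and", "and", "CCONJ"), ("inhibits", "inhibit", "VERB"),
         ("apoptosis", "apoptosis", "NOUN"), (".", ".", "PUNCT")],
        [(2, 1, "nsubj"), (2, 3, "dobj"), (2, 4, "cc"), (2, 5, "conj:and"),
         (5, 6, "dobj"), (2, 7, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p)), (g, 3, _gid(q))],
                 [{"rtype": "ppi", "pair": [p, q]},
                  {"rtype": "component_component", "pair": [p, q]}],
                 [(_gid(p), "GO:0043234"), (_gid(q), "GO:0043234")])


def _t_ppi_multi(rng, cid):
    p, q, r = rng.sample(_PROTEIN_POOL, 3)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("and", "and", "CCONJ"), (q, q.lower(), "PROPN"),
         ("associate", "associate", "VERB"), ("with", "with", "ADP"),
         (r, r.lower(), "PROPN"), (".", ".", "PUNCT")],
        [(4, 1, "nsubj"), (1, 2, "cc"), (1, 3, "conj:and"), (4, 6, "nmod:with"),
         (6, 5, "case"), (4, 7, "punct")],
    )
    pairs = [[p, q], [p, r], [q, r]]
    return _case(
        cid, [g], [(g, 1, _gid(p)), (g, 3, _gid(q)), (g, 6, _gid(r))],
        [{"rtype": "ppi", "pair": pr} for pr in pairs]
        + [{"rtype": "component_component", "pair": pr} for pr in pairs],
        [(_gid(x), "GO:0043234") for x in (p, q, r)],
    )


def _t_ppi_plain(rng, cid):
    # bare two-protein interaction: extracted as ppi, never promoted
    p, q = rng.sample(_PROTEIN_POOL, 2)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("interacts", "interact", "VERB"), ("with", "with", "ADP"),
         (q, q.lower(), "PROPN"), (".", ".", "PUNCT")],
        [(2, 1, "nsubj"), (2, 4, "nmod:with"), (4, 3, "case"), (2, 5, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p)), (g, 4, _gid(q))],
                 [{"rtype": "ppi", "pair": [p, q]}], [])


def _t_staining(rng, cid):
    p = rng.choice(_PROTEIN_POOL)
    loc, go = rng.choice(_LOCATION_POOL)
    s1 = build_sentence(
        cid + ".s1",
        [("The", "the", "DET"), ("localization", "localization", "NOUN"), ("of", "of", "ADP"),
         (p, p.lower(), "PROPN"), ("was", "be", "AUX"), ("examined", "examine", "VERB"),
         (".", ".", "PUNCT")],
        [(2, 1, "det"), (2, 4, "nmod:of"), (4, 3, "case"), (6, 2, "nsubjpass"),
         (6, 5, "auxpass"), (6, 7, "punct")],
    )
    s2 = build_sentence(
        cid + ".s2",
        [("This", "this", "DET"), ("staining", "staining", "NOUN"), ("was", "be", "AUX"),
         ("concentrated", "concentrate", "VERB"), ("in", "in", "ADP"),
         ("the", "the", "DET"), (loc, loc, "NOUN"), (".", ".", "PUNCT")],
        [(2, 1, "det"), (4, 2, "nsubjpass"), (4, 3, "auxpass"), (4, 7, "nmod:in"),
         (7, 5, "case"), (7, 6, "det"), (4, 8, "punct")],
    )
    return _case(cid, [s1, s2], [(s1, 4, _gid(p))],
                 [{"rtype": "staining_in", "protein": p, "location": loc,
                   "confidence": "low"}],
                 [(_gid(p), go)])


def _t_staining_two_proteins(rng, cid):
    # two candidate proteins in the window: uniqueness fails, nothing emitted
    p, q = rng.sample(_PROTEIN_POOL, 2)
    loc, _go = rng.choice(_LOCATION_POOL)
    s1 = build_sentence(
        cid + ".s1",
        [("The", "the", "DET"), ("localization", "localization", "NOUN"), ("of", "of", "ADP"),
         (p, p.lower(), "PROPN"), ("and", "and", "CCONJ"), (q, q.lower(), "PROPN"),
         ("was", "be", "AUX"), ("examined", "examine", "VERB"), (".", ".", "PUNCT")],
        [(2, 1, "det"), (2, 4, "nmod:of"), (4, 3, "case"), (4, 5, "cc"),
         (4, 6, "conj:and"), (8, 2, "nsubjpass"), (8, 7, "auxpass"), (8, 9, "punct")],
    )
    s2 = build_sentence(
        cid + ".s2",
        [("This", "this", "DET"), ("staining", "staining", "NOUN"), ("was", "be", "AUX"),
         ("concentrated", "concentrate", "VERB"), ("in", "in", "ADP"),
         ("the", "the", "DET"), (loc, loc, "NOUN"), (".", ".", "PUNCT")],
        [(2, 1, "det"), (4, 2, "nsubjpass"), (4, 3, "auxpass"), (4, 7, "nmod:in"),
         (7, 5, "case"), (7, 6, "det"), (4, 8, "punct")],
    )
    return _case(cid, [s1, s2], [(s1, 4, _gid(p)), (s1, 6, _gid(q))], [], [])


def _t_nonlocative_distractor(rng, cid):
    # found-in trigger whose modifier is not a locative preposition
    p = rng.choice(_PROTEIN_POOL)
    loc, _go = rng.choice(_LOCATION_POOL)
    g = build_sentence(
        cid + ".s1",
        [(p, p.lower(), "PROPN"), ("was", "be", "AUX"), ("found", "find", "VERB"),
         ("near", "near", "ADP"), ("the", "the", "DET"), (loc, loc, "NOUN"),
         (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 6, "nmod:near"), (6, 4, "case"),
         (6, 5, "det"), (3, 7, "punct")],
    )
    return _case(cid, [g], [(g, 1, _gid(p))], [], [])


def _t_adjectival_distractor(rng, cid):
    # "cytoplasmic P" states existing knowledge; never a finding
    p = rng.choice(_PROTEIN_POOL)
    g = build_sentence(
        cid + ".s1",
        [("The", "the", "DET"), ("cytoplasmic", "cytoplasmic", "ADJ"),
         (p, p.lower(), "PROPN"), ("pool", "pool", "NOUN"),
         ("decreased", "decrease", "VERB"), (".", ".", "PUNCT")],
        [(4, 1, "det"), (4, 2, "amod"), (4, 3, "compound"), (5, 4, "nsubj"),
         (5, 6, "punct")],
    )
    return _case(cid, [g], [(g, 3, _gid(p))], [], [])


_TEMPLATES = (
    _t_found_verbal,
    _t_found_nominal,
    _t_found_adjectival,
    _t_movement_active,
    _t_movement_passive,
    _t_movement_distractor,
    _t_event_pair,
    _t_event_passive,
    _t_partwhole_type1,
    _t_partwhole_type2,
    _t_partwhole_type3,
    _t_formation_form,
    _t_formation_verb,
    _t_formation_nominal,
    _t_ppi_stable,
    _t_ppi_function,
    _t_ppi_multi,
    _t_ppi_plain,
    _t_staining,
    _t_staining_two_proteins,
    _t_nonlocative_distractor,
    _t_adjectival_distractor,
)


def generate_synthetic(n: int, seed: int) -> list[FixtureCase]:
    """``n`` seeded template cases, each with analytically known output.

    Templates cover every rule family plus distractors that must yield
    nothing; the expected relations are recorded by the template
    constructor, independently of the extraction code.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = random.Random(seed)
    out = []
    for i in range(n):
        template = rng.choice(_TEMPLATES)
        out.append(template(rng, f"syn{i}"))
    return out
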