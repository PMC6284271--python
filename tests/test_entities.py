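"""Entity tagging: dictionary locations, complex phrases, stand-off proteins."""

import io

import pytest

from gocc.depgraph import Document, Passage
from gocc.entities import read_standoff_proteins, tag_complexes, tag_locations
from gocc.fixtures import build_sentence, load_fixture
from gocc.lexicons import DataError, LocationDictionary


def test_single_location_mention(cases, loc_dict):
    (g,) = cases["ex4"].sentences
    mentions = tag_locations(g, loc_dict)
    assert [(m.text, m.norm_id) for m in mentions] == [("cytoplasm", "GO:0005737")]
    assert mentions[0].head_token == 7


def test_longest_match_wins_over_nested_entry(cases, loc_dict):
    """'plasma membrane' and 'membrane' are both entries; the longer span
    is tagged once."""
    (g,) = cases["ex8"].sentences
    assert "membrane" in loc_dict and "plasma membrane" in loc_dict
    mentions = tag_locations(g, loc_dict)
    assert [(m.text, m.norm_id) for m in mentions] == [("plasma membrane", "GO:0005886")]


def test_empty_dictionary_tags_nothing(cases):
    (g,) = cases["ex4"].sentences
    assert tag_locations(g, LocationDictionary(entries={}, roots=())) == []


def test_lemma_fallback_matches_inflected_surface(loc_dict):
    g = build_sentence(
        "t1",
        [("Both", "both", "DET"), ("cells", "cell", "NOUN"),
         ("divided", "divide", "VERB"), (".", ".", "PUNCT")],
        [(3, 2, "nsubj"), (2, 1, "det"), (3, 4, "punct")],
    )
    mentions = tag_locations(g, loc_dict)
    assert [(m.text, m.norm_id) for m in mentions] == [("cells", "GO:0005623")]


def _oracle_leftmost_longest(g, entries):
    """All-substrings oracle: at each position take the longest matching
    token span, scanning left to right without overlap."""
    spans, i = [], 0
    toks = g.tokens
    while i < len(toks):
        best = None
        for j in range(i, len(toks)):
            surf = g.text[toks[i].char_start:toks[j].char_end].lower()
            lemmas = " ".join(t.lemma.lower() for t in toks[i:j + 1])
            if surf in entries or lemmas in entries:
                best = j
        if best is None:
            i += 1
        else:
            spans.append((toks[i].char_start, toks[best].char_end))
            i = best + 1
    return spans


@pytest.mark.parametrize("cid", ["ex4", "ex5", "ex6", "ex7", "ex8", "staining"])
def test_tagging_agrees_with_all_substrings_oracle(cid, cases, loc_dict):
    for g in cases[cid].sentences:
        got = [(m.char_start, m.char_end) for m in tag_locations(g, loc_dict)]
        assert got == _oracle_leftmost_longest(g, loc_dict.entries)


def test_location_spans_never_overlap(cases, loc_dict):
    for case in cases.values():
        for g in case.sentences:
            spans = sorted(
                (m.char_start, m.char_end) for m in tag_locations(g, loc_dict)
            )
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                assert e1 <= s2


def test_fterm_phrase_extent_and_head(cases, cx_dict):
    (g,) = cases["ex9"].sentences
    (m,) = tag_complexes(g, cx_dict)
    assert m.etype == "complex_phrase"
    assert m.text == "Aurora B kinase complex"
    assert g.token(m.head_token).text == "complex"
    assert m.norm_id is None


def test_generic_complex_phrase_accepted(cases, cx_dict):
    (g,) = cases["ex14"].sentences
    (m,) = tag_complexes(g, cx_dict)
    assert (m.etype, m.text) == ("complex_phrase", "protein complex")


def test_dictionary_name_subsumes_fterm_phrase(cases, cx_dict):
    (g,) = cases["ex3"].sentences
    mentions = tag_complexes(g, cx_dict)
    assert [(m.etype, m.text, m.norm_id) for m in mentions] == [
        ("complex_name", "eIF3 complex", "GO:0005852")
    ]


def test_no_fterm_no_dictionary_hit(cases, cx_dict):
    (g,) = cases["ex4"].sentences
    assert tag_complexes(g, cx_dict) == []


def test_verbal_fterm_is_not_a_complex_mention(cases, cx_dict):
    (g,) = cases["ex16"].sentences  # "Survivin complexes with Borealin"
    assert tag_complexes(g, cx_dict) == []


def test_standoff_proteins_head_and_tags(cases):
    case = cases["ex2"]
    doc = case.document
    g = case.sentences[0]
    rows = io.StringIO(f"{g.sent_id}\t0\t4\tprotein\tGID:Mad1\n")
    (m,) = read_standoff_proteins(rows, doc)
    assert m.text == "Mad1" and m.head_token == 1 and m.norm_id == "GID:Mad1"
    assert not m.is_tag


def test_standoff_tag_mention_flagged():
    g = build_sentence(
        "t1",
        [("GFP", "gfp", "PROPN"), ("was", "be", "AUX"), ("imaged", "image", "VERB"),
         (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 4, "punct")],
    )
    doc = Document("d", [Passage("results", [g])])
    (m,) = read_standoff_proteins(io.StringIO("t1\t0\t3\tprotein\tGID:GFP\n"), doc)
    assert m.is_tag


def test_standoff_bad_span_reports_row(cases):
    doc = cases["ex2"].document
    with pytest.raises(DataError, match="row 1"):
        read_standoff_proteins(io.StringIO("ex2.s1\t0\t999\tprotein\tX\n"), doc)


def test_standoff_empty_stream(cases):
    assert read_standoff_proteins(io.StringIO(""), cases["ex2"].document) == []
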