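"""Found-in, movement, event-in-location and staining rules."""

import pytest

from gocc.entities import tag_locations
from gocc.fixtures import (
    build_sentence,
    protein_mention,
    relation_signatures,
    run_case,
)
from gocc.location_rules import (
    extract_event_location,
    extract_found_in,
    extract_movement,
    extract_staining,
)
from gocc.depgraph import Document, Passage


def _parts(case, g, loc_dict):
    prots = [m for m in case.proteins if m.sent_id == g.sent_id]
    locs = tag_locations(g, loc_dict)
    return prots, locs


@pytest.mark.parametrize(
    "cid, protein, location, form",
    [
        ("ex4", "SIRT2", "cytoplasm", "verbal"),
        ("ex5", "ZmHK1", "endoplasmic reticulum", "adjectival"),
        ("ex5n", "ZmHK1", "endoplasmic reticulum", "nominal"),
    ],
)
def test_found_in_across_trigger_forms(cid, protein, location, form, cases, loc_dict, lexicon):
    (g,) = cases[cid].sentences
    prots, locs = _parts(cases[cid], g, loc_dict)
    rels = extract_found_in(g, prots, locs, lexicon)
    assert len(rels) == 1
    r = rels[0]
    assert r.participants["protein"].text == protein
    assert r.participants["location"].text == location
    assert r.rule_id == f"found_in.{form}"
    assert r.confidence == "high"


def test_found_in_requires_locative_argument(cases, loc_dict, lexicon):
    g = build_sentence(
        "t1",
        [("Abc1", "abc1", "PROPN"), ("was", "be", "AUX"), ("found", "find", "VERB"),
         ("near", "near", "ADP"), ("the", "the", "DET"),
         ("nucleus", "nucleus", "NOUN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 6, "nmod:near"),
         (6, 4, "case"), (6, 5, "det"), (3, 7, "punct")],
    )
    prots = [protein_mention(g, 1, "GID:Abc1")]
    assert extract_found_in(g, prots, tag_locations(g, loc_dict), lexicon) == []


def test_movement_goal_and_source(cases, loc_dict, lexicon):
    (g,) = cases["ex6"].sentences
    prots, locs = _parts(cases["ex6"], g, loc_dict)
    rels = extract_movement(g, prots, locs, lexicon)
    got = {(r.participants["protein"].text, r.participants["location"].text) for r in rels}
    assert got == {("GLUT4", "cytoplasm"), ("GLUT4", "plasma membrane")}


def test_movement_passive_object_is_the_moved_entity(loc_dict, lexicon):
    g = build_sentence(
        "t1",
        [("ProtY", "proty", "PROPN"), ("was", "be", "AUX"),
         ("recruited", "recruit", "VERB"), ("to", "to", "ADP"), ("the", "the", "DET"),
         ("membrane", "membrane", "NOUN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 6, "nmod:to"), (6, 4, "case"),
         (6, 5, "det"), (3, 7, "punct")],
    )
    prots = [protein_mention(g, 1, "GID:ProtY")]
    (r,) = extract_movement(g, prots, tag_locations(g, loc_dict), lexicon)
    assert r.rtype == "moves" and r.participants["location"].text == "membrane"


def test_movement_rejects_plain_locative_in_by_default(loc_dict, lexicon):
    g = build_sentence(
        "t1",
        [("ProtY", "proty", "PROPN"), ("was", "be", "AUX"),
         ("recruited", "recruit", "VERB"), ("in", "in", "ADP"), ("the", "the", "DET"),
         ("membrane", "membrane", "NOUN"), (".", ".", "PUNCT")],
        [(3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 6, "nmod:in"), (6, 4, "case"),
         (6, 5, "det"), (3, 7, "punct")],
    )
    prots = [protein_mention(g, 1, "GID:ProtY")]
    locs = tag_locations(g, loc_dict)
    assert extract_movement(g, prots, locs, lexicon) == []
    assert len(extract_movement(g, prots, locs, lexicon, accept_locative_in=True)) == 1


def test_event_location_covers_all_participants(cases, loc_dict, lexicon):
    (g,) = cases["ex7"].sentences
    prots, locs = _parts(cases["ex7"], g, loc_dict)
    rels = extract_event_location(g, prots, locs, lexicon)
    got = {(r.participants["protein"].text, r.participants["location"].text) for r in rels}
    assert got == {("Fbxo45", "cytoplasm"), ("Par-4", "cytoplasm")}


def test_event_location_passive_nominalizable(cases, loc_dict, lexicon):
    (g,) = cases["ex8"].sentences
    prots, locs = _parts(cases["ex8"], g, loc_dict)
    (r,) = extract_event_location(g, prots, locs, lexicon)
    assert (r.participants["protein"].text, r.participants["location"].text) == (
        "SGLT1", "plasma membrane",
    )


def test_adjectival_location_yields_nothing(cases):
    """'cytoplasmic CD3' refers to existing knowledge, not a finding."""
    rels, anns = run_case(cases["cd3"])
    assert rels == [] and anns == []


def test_staining_window_and_uniqueness(cases):
    rels, _ = run_case(cases["staining"])
    (r,) = [r for r in rels if r.rtype == "staining_in"]
    assert r.participants["protein"].text == "CeCDC-14"
    assert r.participants["location"].text == "midbody"
    assert r.confidence == "low"


def _staining_doc(lexicon, loc_dict, first_sentence_proteins):
    s1 = build_sentence(
        "d.s1",
        [("The", "the", "DET"), ("signal", "signal", "NOUN"), ("was", "be", "AUX"),
         ("recorded", "record", "VERB"), (".", ".", "PUNCT")],
        [(2, 1, "det"), (4, 2, "nsubjpass"), (4, 3, "auxpass"), (4, 5, "punct")],
    )
    s2 = build_sentence(
        "d.s2",
        [("This", "this", "DET"), ("staining", "staining", "NOUN"), ("was", "be", "AUX"),
         ("seen", "see", "VERB"), ("in", "in", "ADP"), ("the", "the", "DET"),
         ("nucleus", "nucleus", "NOUN"), (".", ".", "PUNCT")],
        [(2, 1, "det"), (4, 2, "nsubjpass"), (4, 3, "auxpass"), (4, 7, "nmod:in"),
         (7, 5, "case"), (7, 6, "det"), (4, 8, "punct")],
    )
    doc = Document("d", [Passage("results", [s1, s2])])
    prots = {"d.s1": first_sentence_proteins, "d.s2": []}
    locs = {"d.s1": [], "d.s2": tag_locations(s2, loc_dict)}
    return extract_staining(doc, prots, locs, lexicon)


def test_staining_needs_exactly_one_candidate(loc_dict, lexicon):
    import dataclasses

    g1 = build_sentence("d.s1", [("X", "x", "PROPN")], [])
    a = dataclasses.replace(protein_mention(g1, 1, "GID:A"), sent_id="d.s1")
    b = dataclasses.replace(a, norm_id="GID:B", text="B")
    gfp = dataclasses.replace(a, norm_id="GID:GFP", text="GFP", is_tag=True)
    assert len(_staining_doc(lexicon, loc_dict, [a])) == 1
    assert _staining_doc(lexicon, loc_dict, [a, b]) == []  # two candidates
    assert _staining_doc(lexicon, loc_dict, [gfp]) == []   # tags never anchor


def test_extraction_is_deterministic(cases):
    for case in cases.values():
        first, _ = run_case(case)
        second, _ = run_case(case)
        assert relation_signatures(first) == relation_signatures(second)
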