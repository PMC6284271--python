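"""Part-whole, formation, PPI extraction and promotion."""

import pytest

from gocc.complex_rules import (
    extract_formation,
    extract_part_whole,
    extract_ppi,
    is_fterm_verb,
    promote_ppi,
)
from gocc.entities import tag_complexes
from gocc.fixtures import build_sentence, protein_mention, run_case


def _parts(case, g, cx_dict):
    prots = [m for m in case.proteins if m.sent_id == g.sent_id]
    return prots, tag_complexes(g, cx_dict)


@pytest.mark.parametrize(
    "cid, expected, rule",
    [
        ("ex9", {("CSC-1", "Aurora B kinase complex")}, "part_whole.type1"),
        ("ex14", {("JAB1", "protein complex")}, "part_whole.type1"),
        ("ex11", {("Rpn10", "26S proteasome")}, "part_whole.type1"),
        ("ex10", {("Sp1", "MRE complex")}, "part_whole.type2"),
        ("ex12", {("Gcn5", "SAGA complex"), ("Ada2", "SAGA complex")}, "part_whole.type2"),
        ("ex13", {("Cdc31", "Sfi1 complex")}, "part_whole.type3"),
    ],
)
def test_part_whole_rule_types(cid, expected, rule, cases, cx_dict, lexicon):
    (g,) = cases[cid].sentences
    prots, cxs = _parts(cases[cid], g, cx_dict)
    rels = extract_part_whole(g, prots, cxs, lexicon)
    got = {
        (r.participants["protein"].text, r.participants["complex"].text) for r in rels
    }
    assert got == expected
    assert {r.rule_id for r in rels} == {rule}


def test_member_collection_expansion_yields_five_components(cases, cx_dict, lexicon):
    (g,) = cases["ex3"].sentences
    prots, cxs = _parts(cases["ex3"], g, cx_dict)
    rels = extract_part_whole(g, prots, cxs, lexicon)
    assert len(rels) == 5
    assert {r.participants["protein"].text for r in rels} == {
        "Rpg1", "Nip1", "Prt1", "Tif34", "Tif35",
    }
    assert {r.participants["complex"].norm_id for r in rels} == {"GO:0005852"}


def test_argument_edges_recorded(cases, cx_dict, lexicon):
    (g,) = cases["ex9"].sentences
    g.added_edges.clear()
    prots, cxs = _parts(cases["ex9"], g, cx_dict)
    extract_part_whole(g, prots, cxs, lexicon)
    labels = {(e.label, e.dependent) for e in g.added_edges}
    assert ("argComponent", 1) in labels and ("argComplex", 10) in labels


@pytest.mark.parametrize(
    "lemma, expected",
    [("dimerize", True), ("complex", True), ("oligomerize", True),
     ("form", False), ("bind", False)],
)
def test_fterm_verb_detection(lemma, expected):
    assert is_fterm_verb(lemma) is expected


def test_formation_fterm_verb_pairs(cases, cx_dict, lexicon):
    for cid, pair in (("ex2", {"Mad1", "Max"}), ("ex16", {"Survivin", "Borealin"})):
        (g,) = cases[cid].sentences
        prots, cxs = _parts(cases[cid], g, cx_dict)
        (r,) = extract_formation(g, prots, cxs, lexicon)
        assert r.rtype == "component_component"
        assert {r.participants["protein"].text, r.participants["protein2"].text} == pair


def test_formation_with_fterm_object(cases, cx_dict, lexicon):
    (g,) = cases["ex15"].sentences
    prots, cxs = _parts(cases["ex15"], g, cx_dict)
    rels = extract_formation(g, prots, cxs, lexicon)
    cc = [r for r in rels if r.rtype == "component_component"]
    po = [r for r in rels if r.rtype == "part_of_complex"]
    assert len(cc) == 1 and len(po) == 2
    assert {r.participants["complex"].text for r in po} == {"tight heterodimer"}


def test_formation_three_subjects_all_pairs(cx_dict, lexicon):
    g = build_sentence(
        "t1",
        [("A1", "a1", "PROPN"), (",", ",", "PUNCT"), ("B2", "b2", "PROPN"),
         ("and", "and", "CCONJ"), ("C3", "c3", "PROPN"), ("form", "form", "VERB"),
         ("a", "a", "DET"), ("trimer", "trimer", "NOUN"), (".", ".", "PUNCT")],
        [(6, 1, "nsubj"), (1, 2, "punct"), (1, 3, "conj:and"), (1, 4, "cc"),
         (1, 5, "conj:and"), (6, 8, "dobj"), (8, 7, "det"), (6, 9, "punct")],
    )
    prots = [protein_mention(g, i, f"GID:{g.token(i).text}") for i in (1, 3, 5)]
    rels = extract_formation(g, prots, tag_complexes(g, cx_dict), lexicon)
    cc = [r for r in rels if r.rtype == "component_component"]
    po = [r for r in rels if r.rtype == "part_of_complex"]
    assert len(cc) == 3 and len(po) == 3  # pairs from the expanded subject list


def test_ppi_pairs_and_expansion(cases, cx_dict, lexicon):
    (g,) = cases["ex18"].sentences
    prots, cxs = _parts(cases["ex18"], g, cx_dict)
    (r,) = extract_ppi(g, prots, lexicon, cxs)
    assert {r.participants["protein"].text, r.participants["protein2"].text} == {
        "CD47", "TSP-1",
    }

    (g,) = cases["ex19"].sentences
    prots, cxs = _parts(cases["ex19"], g, cx_dict)
    rels = extract_ppi(g, prots, lexicon, cxs)
    pairs = {
        frozenset((r.participants["protein"].text, r.participants["protein2"].text))
        for r in rels
    }
    assert pairs == {
        frozenset(("Bmh1p", "Bmh2p")),
        frozenset(("Bmh1p", "Ste20p")),
        frozenset(("Bmh2p", "Ste20p")),
    }


def test_no_ppi_without_trigger(cases, cx_dict, lexicon):
    (g,) = cases["ex4"].sentences
    prots, cxs = _parts(cases["ex4"], g, cx_dict)
    assert extract_ppi(g, prots, lexicon, cxs) == []


def _promote(cases, cid, cx_dict, lexicon):
    (g,) = cases[cid].sentences
    prots, cxs = _parts(cases[cid], g, cx_dict)
    ppi = extract_ppi(g, prots, lexicon, cxs)
    return ppi, promote_ppi(g, ppi, lexicon, prots, cxs)


def test_promotion_by_conjoined_function_verb(cases, cx_dict, lexicon):
    _, promoted = _promote(cases, "ex18", cx_dict, lexicon)
    (r,) = promoted
    assert r.promotion.basis == "function"
    assert r.rtype == "component_component"


def test_promotion_by_stability_marker(cases, cx_dict, lexicon):
    _, promoted = _promote(cases, "ex17", cx_dict, lexicon)
    (r,) = promoted
    assert r.promotion.basis == "stable"


def test_promotion_by_participant_count(cases, cx_dict, lexicon):
    ppi, promoted = _promote(cases, "ex19", cx_dict, lexicon)
    assert len(promoted) == 3
    assert all(r.promotion == promoted[0].promotion for r in promoted)
    assert promoted[0].promotion.basis == "multi_component"
    assert promoted[0].promotion.detail == 3


def test_unnamed_complex_partner_supports_promotion(cases, cx_dict, lexicon):
    ppi, promoted = _promote(cases, "ex20", cx_dict, lexicon)
    (p,) = ppi
    assert p.participants["complex"].etype == "complex_phrase"
    (r,) = promoted
    assert r.rtype == "part_of_complex"
    assert r.participants["protein"].text == "CAR-1"
    assert r.promotion.basis == "multi_component"


def test_plain_two_protein_interaction_not_promoted(cases, cx_dict, lexicon):
    ppi, promoted = _promote(cases, "ex7", cx_dict, lexicon)
    assert len(ppi) == 1 and promoted == []


def test_promotion_never_invents_pairs(cases, cx_dict, lexicon):
    for cid in ("ex17", "ex18", "ex19", "ex20"):
        ppi, promoted = _promote(cases, cid, cx_dict, lexicon)
        ppi_pairs = {
            frozenset(m.text for m in r.participants.values()) for r in ppi
        }
        for r in promoted:
            assert frozenset(m.text for m in r.participants.values()) in ppi_pairs


def test_component_relations_are_symmetric(cases):
    for case in cases.values():
        rels, _ = run_case(case)
        for r in rels:
            if r.rtype in ("component_component", "ppi") and "protein2" in r.participants:
                a, b = r.participants["protein"], r.participants["protein2"]
                swapped = dict(r.participants, protein=b, protein2=a)
                import dataclasses

                mirror = dataclasses.replace(r, participants=swapped)
                assert mirror.signature() == r.signature()
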