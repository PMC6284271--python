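"""Dictionary building, f-term matching and trigger configuration."""

import io
import random
import re

import obonet
import pytest

from gocc.lexicons import (
    ConfigError,
    DataError,
    SUBCELLULAR_ROOTS,
    TriggerLexicon,
    build_complex_dictionary,
    build_location_dictionary,
    default_triggers,
    is_complex_fterm,
    load_triggers,
    packaged_data,
)

TOY_OBO = """\
format-version: 1.2
ontology: test

[Term]
id: GO:0005623
name: cell

[Term]
id: GO:0000001
name: toyplasm
synonym: "toy matrix" EXACT []
is_a: GO:0005623 ! cell

[Term]
id: GO:0000002
name: toysol
relationship: part_of GO:0000001 ! toyplasm

[Term]
id: GO:0000003
name: orphan thing
"""


def _reachability_oracle(obo_text: str, roots: set[str]) -> set[str]:
    """Independent oracle: exhaustive upward DFS per node over the raw
    is_a/relationship attributes, no shared code with the implementation."""
    graph = obonet.read_obo(io.StringIO(obo_text))
    parents = {}
    for node, data in graph.nodes(data=True):
        ps = list(data.get("is_a", []))
        for rel in data.get("relationship", []):
            kind, target = rel.split(" ", 1)
            if kind == "part_of":
                ps.append(target.strip())
        parents[node] = ps

    def reaches_root(node, seen=()):
        if node in roots:
            return True
        return any(
            p not in seen and reaches_root(p, seen + (node,))
            for p in parents.get(node, ())
        )

    return {n for n in parents if reaches_root(n)}


def test_toy_closure_matches_reachability_oracle():
    d = build_location_dictionary(io.StringIO(TOY_OBO), roots=["GO:0005623"])
    expected_ids = _reachability_oracle(TOY_OBO, {"GO:0005623"})
    assert set(d.entries.values()) == expected_ids
    assert d.entries["toyplasm"] == "GO:0000001"
    assert d.entries["cell"] == "GO:0005623"
    assert d.entries["toy matrix"] == "GO:0000001"  # exact synonym
    assert "orphan thing" not in d.entries  # no path to a root


def test_is_a_only_mode_excludes_part_of_descendants():
    d = build_location_dictionary(
        io.StringIO(TOY_OBO), roots=["GO:0005623"], relations=("is_a",)
    )
    assert "toysol" not in d.entries
    assert "toyplasm" in d.entries


def test_missing_root_is_named_in_error():
    with pytest.raises(ConfigError, match="GO:9999999"):
        build_location_dictionary(io.StringIO(TOY_OBO), roots=["GO:9999999"])


def test_packaged_ontology_with_full_root_list():
    d = build_location_dictionary(io.StringIO(packaged_data("go_cc_subset_synthetic.obo")))
    assert len(d.roots) == 19
    assert d.get("membrane") == "GO:0016020"
    assert d.get("Cell") == "GO:0005623"  # case-insensitive
    assert d.get("cytosol") == "GO:0005829"  # part_of closure
    assert d.get("protein complex") is None  # complex branch is not a location
    assert d.get("biological_process") is None


@pytest.mark.parametrize(
    "rows, query, expected",
    [
        (["eIF3 complex\tGO:0005852"], "eif3 complex", "GO:0005852"),
        (["eIF3 complex\tGO:0005852"], "EIF3 COMPLEX", "GO:0005852"),
        ([], "anything", None),
    ],
)
def test_complex_dictionary_lookup_is_case_insensitive(rows, query, expected):
    cd = build_complex_dictionary(rows)
    assert cd.get(query) == expected


def test_complex_dictionary_conflicts_rejected():
    with pytest.raises(DataError, match="C"):
        build_complex_dictionary(["C\tGO:0000001", "C\tGO:0000002"])
    # exact duplicates are fine
    cd = build_complex_dictionary(["C\tGO:0000001", "C\tGO:0000001"])
    assert cd.get("c") == "GO:0000001"


_FTERM_SUFFIXES = (
    "complex", "dimer", "trimer", "tramer", "hexamer",
    "nonamer", "tamer", "decamer", "octomer", "oligomer",
)


@pytest.mark.parametrize(
    "word, expected",
    [
        ("complex", True),
        ("heterodimer", True),
        ("trimer", True),
        ("oligomer", True),
        ("tetramer", True),   # suffix "tramer"
        ("pentamer", True),   # suffix "tamer"
        ("octamer", True),    # suffix "tamer"
        ("complexity", False),
        ("dimerization", False),
        ("proteasome", False),
        ("Complex", True),
    ],
)
def test_fterm_examples(word, expected):
    assert is_complex_fterm(word) is expected


def test_fterm_matches_brute_force_suffix_oracle():
    rng = random.Random(0)
    vocab = ["protein", "kinase", "dimer", "homodimer", "complex", "plex",
             "decamer", "monomer", "hexamer", "spectrometer", "parameter",
             "octomer", "octamer", "oligomer", "polymer", "tamer", "stream"]
    for _ in range(500):
        word = rng.choice(vocab) + rng.choice(["", "s"[:0], ""])  # plain tokens
        word = rng.choice([word, word.upper(), word.capitalize()])
        oracle = any(word.lower().endswith(s) for s in _FTERM_SUFFIXES)
        assert is_complex_fterm(word) is oracle


def test_default_triggers_cover_designed_vocabulary():
    lex = default_triggers()
    assert {"found", "detected", "localized"} <= lex.entries("found_in")
    assert {"subunit", "component"} <= lex.entries("part_whole_noun")
    assert {"contain", "consist"} <= lex.entries("containment_verb")
    assert {"interact", "bind", "associate"} <= lex.entries("ppi")
    assert "form" in lex.entries("formation")
    assert "staining" in lex.entries("staining")
    assert "GFP" in lex.tags


def test_unknown_trigger_class_rejected():
    with pytest.raises(ConfigError, match="made_up"):
        load_triggers("made_up: [x]")
    with pytest.raises(ConfigError):
        TriggerLexicon(classes={"nope": frozenset({"x"})})


def test_empty_config_gives_empty_lexicon():
    lex = load_triggers("")
    assert all(not lex.entries(c) for c in lex.classes)
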