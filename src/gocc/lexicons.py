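"""Dictionaries and trigger lexicon.

Two GO Cellular Component sub-hierarchies drive the annotation task:

* **subcellular locations** — every term reachable from 19 root terms
  (:data:`SUBCELLULAR_ROOTS`, all direct children of ``cellular_component``)
  through ``is_a``/``part_of`` edges;
* **protein complexes** — the sub-hierarchy under ``protein complex``
  (:data:`GO_PROTEIN_COMPLEX`), plus complex names curated by resources such
  as PRO, the Complex Portal and CORUM, shipped here as a TSV name→GO map.

A *trigger* is a word whose presence, with the right dependency structure
around it, signals a relation ("subunit", "dimerizes", "found").  Trigger
inventories are configuration, not code: :func:`load_triggers` reads a YAML
map of trigger class → lemma list, and the packaged default is seeded from
the words the method was designed around.

Protein-complex *f-terms* are head nouns whose suffix marks the phrase as
denoting a complex ("complex", "heterodimer", "oligomer"); the suffix set
is matched verbatim by :func:`is_complex_fterm`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, TextIO

import networkx as nx
import obonet
import yaml

from .depgraph import Token

__all__ = [
    "SUBCELLULAR_ROOTS",
    "GO_PROTEIN_COMPLEX",
    "GO_ID_RE",
    "TRIGGER_CLASSES",
    "LocationDictionary",
    "ComplexDictionary",
    "TriggerLexicon",
    "ConfigError",
    "DataError",
    "build_location_dictionary",
    "build_complex_dictionary",
    "descendant_closure",
    "is_complex_fterm",
    "load_triggers",
    "default_triggers",
    "packaged_data",
]

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: Generic "protein complex" term — the fallback annotation when a complex
#: mention cannot be linked to a more specific GO entry.
GO_PROTEIN_COMPLEX = "GO:0043234"

#: The 19 root terms of the subcellular-location sub-hierarchies (all are
#: direct children of cellular_component, GO:0005575).
SUBCELLULAR_ROOTS: dict[str, str] = {
    "GO:0005576": "extracellular region",
    "GO:0005623": "cell",
    "GO:0009295": "nucleoid",
    "GO:0016020": "membrane",
    "GO:0019012": "virion",
    "GO:0030054": "cell junction",
    "GO:0031012": "extracellular matrix",
    "GO:0031974": "membrane-enclosed lumen",
    "GO:0039679": "viral occlusion body",
    "GO:0043226": "organelle",
    "GO:0044420": "extracellular matrix component",
    "GO:0044421": "extracellular region part",
    "GO:0044422": "organelle part",
    "GO:0044423": "virion part",
    "GO:0044425": "membrane part",
    "GO:0044456": "synapse part",
    "GO:0044464": "cell part",
    "GO:0045202": "synapse",
    "GO:0055044": "symplast",
}

#: Closed set of trigger classes.
TRIGGER_CLASSES = frozenset(
    {
        "found_in",
        "movement",
        "event",
        "part_whole_noun",
        "containment_verb",
        "detected_in",
        "formation",
        "ppi",
        "stability_marker",
        "staining",
    }
)


class ConfigError(ValueError):
    """Bad dictionary/lexicon configuration (unknown class, missing root...)."""


class DataError(ValueError):
    """Inconsistent input data (conflicting mappings, bad spans...)."""


# ---------------------------------------------------------------------------
# location dictionary


@dataclass
class LocationDictionary:
    """Case-insensitive map from location surface strings to GO IDs."""

    entries: dict[str, str]
    roots: tuple[str, ...]

    def get(self, name: str) -> str | None:
        return self.entries.get(name.lower())

    def __contains__(self, name: str) -> bool:
        return name.lower() in self.entries

    def go_ids(self) -> set[str]:
        return set(self.entries.values())


_SYNONYM_RE = re.compile(r'^"(.*)"\s+(\w+)')


def _exact_synonyms(node_data: dict) -> list[str]:
    out = []
    for raw in node_data.get("synonym", ()):
        m = _SYNONYM_RE.match(raw)
        if m and m.group(2) == "EXACT":
            out.append(m.group(1))
    return out


def descendant_closure(
    graph: nx.MultiDiGraph, root: str, relations: tuple[str, ...] = ("is_a", "part_of")
) -> set[str]:
    """All terms reachable *down* from ``root`` via the given relations.

    OBO graphs point child → parent, so this is a reverse breadth-first
    search over edges whose key is an allowed relation.  ``root`` itself is
    included.
    """
    members = {root}
    frontier = [root]
    while frontier:
        node = frontier.pop()
        for child, _parent, key in graph.in_edges(node, keys=True):
            if key in relations and child not in members:
                members.add(child)
                frontier.append(child)
    return members


def build_location_dictionary(
    obo: TextIO | str,
    roots: Iterable[str] | None = None,
    *,
    include_synonyms: bool = True,
    relations: tuple[str, ...] = ("is_a", "part_of"),
) -> LocationDictionary:
    """Build the subcellular-location dictionary from an OBO ontology.

    ``entries`` collects the primary name (and, by default, exact synonyms)
    of every term in the closure of the root set under ``relations``.
    A root absent from the ontology raises :class:`ConfigError` naming it.
    """
    graph = obonet.read_obo(obo)
    root_ids = tuple(roots) if roots is not None else tuple(SUBCELLULAR_ROOTS)
    members: set[str] = set()
    for root in root_ids:
        if root not in graph:
            raise ConfigError(f"root term {root} not present in the ontology")
        members |= descendant_closure(graph, root, relations)

    entries: dict[str, str] = {}
    for go_id in sorted(members):
        data = graph.nodes[go_id]
        names = [data.get("name", "")]
        if include_synonyms:
            names += _exact_synonyms(data)
        for name in names:
            if name:
                entries.setdefault(name.lower(), go_id)
    return LocationDictionary(entries=entries, roots=root_ids)


# ---------------------------------------------------------------------------
# complex dictionary


@dataclass
class ComplexDictionary:
    """Case-insensitive complex name → GO ID map.

    An empty-string value means the name is known but has no GO link; such
    mentions fall back to the generic ``protein complex`` term at
    annotation time.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def get(self, name: str) -> str | None:
        return self.entries.get(name.lower())

    def __contains__(self, name: str) -> bool:
        return name.lower() in self.entries


def build_complex_dictionary(mapping: TextIO | Iterable[str]) -> ComplexDictionary:
    """Read ``name<TAB>go_id`` rows (go_id may be blank).

    Duplicate names with conflicting GO IDs raise :class:`DataError` listing
    the names; exact duplicates are tolerated.  A ``name``/``go_id`` header
    row is skipped.
    """
    entries: dict[str, str] = {}
    conflicts: list[str] = []
    for row in csv.reader(mapping, delimiter="\t"):
        if not row or not row[0].strip() or row[0].startswith("#"):
            continue
        name = row[0].strip()
        go_id = row[1].strip() if len(row) > 1 else ""
        if name.lower() == "name" and go_id.lower() in ("go_id", "goid"):
            continue
        if go_id and not GO_ID_RE.match(go_id):
            raise DataError(f"invalid GO identifier {go_id!r} for complex {name!r}")
        key = name.lower()
        if key in entries and entries[key] != go_id:
            conflicts.append(name)
        else:
            entries[key] = go_id
    if conflicts:
        raise DataError(
            "conflicting GO mappings for complex names: " + ", ".join(sorted(set(conflicts)))
        )
    return ComplexDictionary(entries=entries)


# ---------------------------------------------------------------------------
# f-term matcher

#: Suffix alternatives matched verbatim.  Note the suffixes already cover
#: more surface forms than they literally spell: "tetramer" ends in
#: "tramer" and "pentamer"/"octamer" end in "tamer".
_FTERM_RE = re.compile(
    r"(complex|dimer|trimer|tramer|hexamer|nonamer|tamer|decamer|octomer|oligomer)$"
)
_FTERM_EXTENDED_RE = re.compile(
    r"(complex|dimer|trimer|tramer|tetramer|pentamer|hexamer|nonamer|tamer|"
    r"decamer|octomer|octamer|oligomer)$"
)


def is_complex_fterm(word: str, *, extended: bool = False) -> bool:
    """True iff ``word`` (lowercased) ends with a protein-complex f-term suffix."""
    pattern = _FTERM_EXTENDED_RE if extended else _FTERM_RE
    return bool(pattern.search(word.lower()))


# ---------------------------------------------------------------------------
# trigger lexicon

#: Fluorescence/affinity tag names; a "protein" mention whose surface is a
#: tag must not anchor a staining inference.
DEFAULT_TAGS = frozenset(
    {"GFP", "EGFP", "YFP", "RFP", "CFP", "mCherry", "HA", "FLAG", "His", "Myc", "V5", "GST"}
)


@dataclass
class TriggerLexicon:
    """Lemma sets per trigger class; classes may overlap."""

    classes: dict[str, frozenset[str]]
    tags: frozenset[str] = DEFAULT_TAGS

    def __post_init__(self) -> None:
        unknown = set(self.classes) - TRIGGER_CLASSES
        if unknown:
            raise ConfigError(f"unknown trigger classes: {sorted(unknown)}")
        self.classes = {
            c: frozenset(w.lower() for w in ws) for c, ws in self.classes.items()
        }
        for c in TRIGGER_CLASSES:
            self.classes.setdefault(c, frozenset())

    def entries(self, tclass: str) -> frozenset[str]:
        if tclass not in TRIGGER_CLASSES:
            raise ConfigError(f"unknown trigger class {tclass!r}")
        return self.classes[tclass]

    def matches(self, token: Token, tclass: str) -> bool:
        """A token matches a class via its lemma or lowercased surface form."""
        entries = self.entries(tclass)
        return token.lemma.lower() in entries or token.text.lower() in entries


def load_triggers(config: TextIO | str) -> TriggerLexicon:
    """Load a trigger lexicon from YAML (``class: [lemma, ...]``).

    The optional ``tags`` key lists tag names (GFP etc.); any other key
    outside the ten trigger classes raises :class:`ConfigError`.
    """
    data = yaml.safe_load(config) or {}
    if not isinstance(data, dict):
        raise ConfigError("trigger config must be a mapping of class -> lemma list")
    tags = data.pop("tags", None)
    unknown = set(data) - TRIGGER_CLASSES
    if unknown:
        raise ConfigError(f"unknown trigger classes: {sorted(unknown)}")
    classes = {c: frozenset(map(str, ws or ())) for c, ws in data.items()}
    return TriggerLexicon(
        classes=classes,
        tags=frozenset(map(str, tags)) if tags is not None else DEFAULT_TAGS,
    )


def packaged_data(name: str) -> str:
    """Return the text of a packaged data file (``gocc/data/<name>``)."""
    return resources.files("gocc").joinpath("data", name).read_text(encoding="utf-8")


def default_triggers() -> TriggerLexicon:
    """The packaged default trigger lexicon."""
    return load_triggers(packaged_data("triggers.yaml"))
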