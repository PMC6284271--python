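"""Map relations to GO terms and assemble document-level annotations.

The end product is a set of (document, gene, GO-ID) triplets.  Location
relations map directly to the location mention's GO term.  Complex
relations map through the complex-name dictionary when possible; a complex
phrase ("a protein complex") or an unlinked name falls back to the generic
``protein complex`` term GO:0043234.  GO terms are species-independent, so
no species handling is needed at lookup time.

Following curation practice, predictions are restricted to the abstract,
results, discussion and conclusion sections (:func:`filter_sections`).
Low-confidence (staining) evidence is included by default — it contributes
recall — and can be excluded with ``high_confidence_only``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .complex_rules import (
    extract_formation,
    extract_part_whole,
    extract_ppi,
    promote_ppi,
)
from .depgraph import Document
from .entities import EntityMention, tag_complexes, tag_locations
from .lexicons import (
    ComplexDictionary,
    GO_ID_RE,
    GO_PROTEIN_COMPLEX,
    LocationDictionary,
    TriggerLexicon,
)
from .location_rules import (
    LOCATION_RELATION_TYPES,
    Relation,
    extract_event_location,
    extract_found_in,
    extract_movement,
    extract_staining,
)

__all__ = [
    "GOAnnotation",
    "SECTION_KEYWORDS",
    "filter_sections",
    "map_location",
    "map_complex",
    "assemble",
    "extract_relations",
    "annotate_document",
]

#: Normalized section labels retained for prediction.
SECTION_KEYWORDS = frozenset({"abstract", "results", "result", "discussion", "conclusion", "conclusions"})


@dataclass
class GOAnnotation:
    """A (doc, gene, GO-ID) triplet with its evidence trail."""

    doc_id: str
    gene_id: str
    go_id: str
    evidence: list[tuple[str, str, str]] = field(default_factory=list)
    # evidence items: (sent_id, rule_id, confidence)

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.go_id):
            raise ValueError(f"invalid GO identifier {self.go_id!r}")
        if not self.evidence:
            raise ValueError("annotation requires at least one evidenced rule firing")

    @property
    def confidence(self) -> str:
        return "high" if any(c == "high" for _s, _r, c in self.evidence) else "low"

    def triplet(self) -> tuple[str, str, str]:
        return (self.doc_id, self.gene_id, self.go_id)


def _normalize_label(label: str) -> set[str]:
    words = set(re.split(r"[^a-z]+", label.lower()))
    return words & SECTION_KEYWORDS


def filter_sections(doc: Document, *, strict: bool = False) -> Document:
    """Keep abstract/results/discussion/conclusion passages.

    Combined headings ("Results and Discussion") are retained because label
    matching is by keyword.  If *no* passage label is recognizable the
    whole document is kept with a warning (set ``strict=True`` to drop
    instead).
    """
    kept = [p for p in doc.passages if _normalize_label(p.section)]
    if not kept:
        warnings.warn(
            f"{doc.doc_id}: no recognizable section labels; "
            + ("dropping all passages" if strict else "keeping the whole document"),
            stacklevel=2,
        )
        return Document(doc.doc_id, []) if strict else doc
    return Document(doc.doc_id, kept)


def map_location(m: EntityMention) -> str:
    """GO ID of a location mention (assigned at tagging time)."""
    if m.etype != "location":
        raise ValueError(f"map_location expects a location mention, got {m.etype}")
    assert m.norm_id is not None
    return m.norm_id


def map_complex(m: EntityMention, cd: ComplexDictionary | None = None) -> str:
    """GO ID for a complex mention; GO:0043234 when nothing better is known."""
    if m.etype not in ("complex_name", "complex_phrase"):
        raise ValueError(f"map_complex expects a complex mention, got {m.etype}")
    if m.norm_id:
        return m.norm_id
    if cd is not None:
        linked = cd.get(m.text)
        if linked:
            return linked
    return GO_PROTEIN_COMPLEX


def assemble(
    doc_id: str,
    relations: Sequence[Relation],
    cd: ComplexDictionary | None = None,
    *,
    high_confidence_only: bool = False,
) -> list[GOAnnotation]:
    """Turn relations into deduplicated, deterministically ordered triplets.

    Proteins without a normalized gene ID contribute nothing.  ``ppi``
    relations are interaction evidence only and never annotated directly —
    promotion decides whether they imply a complex.
    """
    acc: dict[tuple[str, str, str], list[tuple[str, str, str]]] = {}

    def record(m: EntityMention, go_id: str, r: Relation) -> None:
        if not m.norm_id:
            return
        acc.setdefault((doc_id, m.norm_id, go_id), []).append(
            (r.sent_id, r.rule_id, r.confidence)
        )

    for r in relations:
        if high_confidence_only and r.confidence == "low":
            continue
        if r.rtype in LOCATION_RELATION_TYPES:
            record(r.participants["protein"], map_location(r.participants["location"]), r)
        elif r.rtype == "part_of_complex":
            go_id = map_complex(r.participants["complex"], cd)
            record(r.participants["protein"], go_id, r)
        elif r.rtype == "component_component":
            cxm = r.participants.get("complex")
            go_id = map_complex(cxm, cd) if cxm is not None else GO_PROTEIN_COMPLEX
            record(r.participants["protein"], go_id, r)
            record(r.participants["protein2"], go_id, r)

    return [
        GOAnnotation(d, g, go, evidence)
        for (d, g, go), evidence in sorted(acc.items())
    ]


# ---------------------------------------------------------------------------
# pipeline


def extract_relations(
    doc: Document,
    proteins: Sequence[EntityMention],
    loc_dict: LocationDictionary,
    cx_dict: ComplexDictionary | None,
    lex: TriggerLexicon,
) -> list[Relation]:
    """Run every rule family over a document and return all relations."""
    relations: list[Relation] = []
    proteins_by_sent: dict[str, list[EntityMention]] = {}
    locations_by_sent: dict[str, list[EntityMention]] = {}
    for m in proteins:
        proteins_by_sent.setdefault(m.sent_id, []).append(m)

    for g in doc.sentences():
        locs = tag_locations(g, loc_dict)
        cxs = tag_complexes(g, cx_dict)
        prots = proteins_by_sent.get(g.sent_id, [])
        locations_by_sent[g.sent_id] = locs

        relations += extract_found_in(g, prots, locs, lex)
        relations += extract_movement(g, prots, locs, lex)
        relations += extract_event_location(g, prots, locs, lex)
        relations += extract_part_whole(g, prots, cxs, lex)
        relations += extract_formation(g, prots, cxs, lex)
        ppi = extract_ppi(g, prots, lex, cxs)
        relations += ppi
        relations += promote_ppi(g, ppi, lex, prots, cxs)

    relations += extract_staining(doc, proteins_by_sent, locations_by_sent, lex)
    return relations


def annotate_document(
    doc: Document,
    proteins: Sequence[EntityMention],
    loc_dict: LocationDictionary,
    cx_dict: ComplexDictionary | None,
    lex: TriggerLexicon,
    *,
    apply_section_filter: bool = True,
    high_confidence_only: bool = False,
) -> tuple[list[Relation], list[GOAnnotation]]:
    """Full pipeline: section filter → tagging → rules → triplets."""
    if apply_section_filter:
        doc = filter_sections(doc)
    relations = extract_relations(doc, proteins, loc_dict, cx_dict, lex)
    annotations = assemble(
        doc.doc_id, relations, cx_dict, high_confidence_only=high_confidence_only
    )
    return relations, annotations
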