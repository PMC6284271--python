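"""Protein–subcellular-location relation extraction.

Four rule families relate a protein to a location:

* **found-in** — an explicit localization trigger ("found", "detected",
  "localized", also nominal "detection (of X) in Y" and adjectival
  "X is present in Y") with the location as a locative prepositional
  modifier (``nmod:in``/``at``/``on``...);
* **movement** — a movement verb whose moved entity is the protein and
  whose goal/source is the location; these verbs select directional
  prepositions (``nmod:to``/``from``/``into``), not locative ``in``;
* **event-in-location** — the protein is an argument of some event
  ("interacts", "is expressed") that carries a locative modifier, so the
  protein must have been there;
* **staining** — fluorescence-microscopy descriptions ("this staining
  compacted to ..."); a low-confidence heuristic that requires a location
  in the staining sentence and a *unique* non-tag protein in the same or
  previous sentence.

Adjectival location premodifiers of a protein ("cytoplasmic CD3") are
deliberately not a rule: they state existing knowledge, not a finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .depgraph import (
    Document,
    OBJECT_LABELS,
    PASSIVE_SUBJECT_LABELS,
    SUBJECT_LABELS,
    SentenceGraph,
    add_argument_edge,
)
from .entities import EntityMention
from .lexicons import TriggerLexicon
from .propagation import expand_member_collection, resolve_copular

__all__ = [
    "Relation",
    "TriggerMatch",
    "PromotionEvidence",
    "LOCATIVE_PREPOSITIONS",
    "MOVEMENT_PREPOSITIONS",
    "find_triggers",
    "extract_found_in",
    "extract_movement",
    "extract_event_location",
    "extract_staining",
]

RelationType = Literal[
    "found_in",
    "moves",
    "event_in",
    "staining_in",
    "part_of_complex",
    "component_component",
    "ppi",
]

LOCATION_RELATION_TYPES = ("found_in", "moves", "event_in", "staining_in")

#: Prepositions accepted as locative for found-in and event rules.
LOCATIVE_PREPOSITIONS = ("in", "at", "on", "within", "inside")
#: Prepositions accepted for movement goals/sources.
MOVEMENT_PREPOSITIONS = ("to", "from", "into", "toward", "towards")

_FORM_BY_POS = {"VERB": "verbal", "AUX": "verbal", "NOUN": "nominal", "ADJ": "adjectival"}


@dataclass(frozen=True)
class TriggerMatch:
    """A token matched against the trigger lexicon."""

    token: int
    tclass: str
    form: Literal["verbal", "nominal", "adjectival"]


@dataclass(frozen=True)
class PromotionEvidence:
    """Why a PPI was promoted to complex co-membership.

    ``detail`` is the supporting token index (stability marker or conjoined
    function verb) or, for ``multi_component``, the participant count.
    """

    basis: Literal["stable", "function", "multi_component"]
    detail: int

    def __post_init__(self) -> None:
        if self.basis == "multi_component" and self.detail < 3:
            raise ValueError("multi_component promotion requires >= 3 participants")


@dataclass
class Relation:
    """An extracted assertion with its full audit trail.

    ``participants`` maps roles (``protein``, ``protein2``, ``location``,
    ``complex``) to mentions; ``rule_id`` names the rule that fired.
    """

    rtype: RelationType
    participants: dict[str, EntityMention]
    trigger: TriggerMatch
    sent_id: str
    confidence: Literal["high", "low"] = "high"
    rule_id: str = ""
    promotion: PromotionEvidence | None = None

    def __post_init__(self) -> None:
        roles = set(self.participants)
        if self.rtype in LOCATION_RELATION_TYPES:
            required = {"protein", "location"}
        elif self.rtype == "part_of_complex":
            required = {"protein", "complex"}
        elif self.rtype == "component_component":
            required = {"protein", "protein2"}
        elif self.rtype == "ppi":
            # unnamed-partner contexts: a single named protein with a
            # complex-phrase partner is a valid PPI context for promotion
            if "protein" not in roles or not ({"protein2", "complex"} & roles):
                raise ValueError(f"ppi relation needs protein and a partner, got {roles}")
            required = set()
        else:
            raise ValueError(f"unknown relation type {self.rtype!r}")
        if not required <= roles:
            raise ValueError(f"{self.rtype} relation missing roles {required - roles}")
        if self.rtype == "staining_in" and self.confidence != "low":
            raise ValueError("staining relations are low-confidence by definition")

    def signature(self) -> tuple:
        """Order-insensitive comparison key (symmetric relations unordered)."""
        if self.rtype in ("component_component", "ppi"):
            pair = tuple(
                sorted(
                    m.text
                    for r, m in self.participants.items()
                    if r in ("protein", "protein2")
                )
            )
            rest = tuple(
                sorted(
                    (r, m.text) for r, m in self.participants.items()
                    if r not in ("protein", "protein2")
                )
            )
            return (self.rtype, pair, rest, self.confidence)
        return (
            self.rtype,
            tuple(sorted((r, m.text) for r, m in self.participants.items())),
            (),
            self.confidence,
        )


# ---------------------------------------------------------------------------
# shared helpers


def find_triggers(g: SentenceGraph, lex: TriggerLexicon, tclass: str) -> list[TriggerMatch]:
    """Tokens of ``g`` whose lemma (or surface) is listed for ``tclass``."""
    out = []
    for t in g.tokens:
        if lex.matches(t, tclass):
            out.append(TriggerMatch(t.index, tclass, _FORM_BY_POS.get(t.pos, "verbal")))
    return out


def _by_head(mentions: Iterable[EntityMention]) -> dict[int, EntityMention]:
    return {m.head_token: m for m in mentions}


def _expand_to_mentions(
    g: SentenceGraph, tokens: Iterable[int], mentions_by_head: dict[int, EntityMention]
) -> list[EntityMention]:
    """Member-collection-expand each token and keep those that are mentions."""
    out: list[EntityMention] = []
    seen: set[int] = set()
    for tok in tokens:
        for member in expand_member_collection(g, tok):
            if member in mentions_by_head and member not in seen:
                seen.add(member)
                out.append(mentions_by_head[member])
    return out


def _nmod_targets(
    g: SentenceGraph,
    head: int,
    prepositions: Sequence[str],
    mentions_by_head: dict[int, EntityMention],
) -> list[EntityMention]:
    out = []
    for prep in prepositions:
        for dep in g.dependents(head, f"nmod:{prep}"):
            for member in expand_member_collection(g, dep):
                if member in mentions_by_head:
                    out.append(mentions_by_head[member])
    return out


def _protein_args(
    g: SentenceGraph,
    tm: TriggerMatch,
    proteins_by_head: dict[int, EntityMention],
    *,
    labels: Sequence[str],
    nominal_labels: Sequence[str] = ("nmod:of", "compound"),
) -> list[EntityMention]:
    """Protein arguments of a trigger, honoring its syntactic form."""
    if tm.form == "nominal":
        arg_tokens = []
        for label in nominal_labels:
            arg_tokens += g.dependents(tm.token, label)
        # predicate nominals ("X is the subunit ...") still take a subject
        subj = resolve_copular(g, tm.token)
        if subj != tm.token:
            arg_tokens.append(subj)
    else:
        arg_tokens = []
        for label in labels:
            arg_tokens += g.dependents(tm.token, label)
        if not arg_tokens and tm.form == "adjectival":
            subj = resolve_copular(g, tm.token)
            if subj != tm.token:
                arg_tokens.append(subj)
    return _expand_to_mentions(g, arg_tokens, proteins_by_head)


def _emit_location(
    g: SentenceGraph,
    rtype: str,
    rule_id: str,
    tm: TriggerMatch,
    proteins: list[EntityMention],
    locations: list[EntityMention],
    confidence: str = "high",
) -> list[Relation]:
    out = []
    for p in proteins:
        for loc in locations:
            add_argument_edge(g, tm.token, p.head_token, "argComponent")
            add_argument_edge(g, tm.token, loc.head_token, "argLocation")
            out.append(
                Relation(
                    rtype=rtype,
                    participants={"protein": p, "location": loc},
                    trigger=tm,
                    sent_id=g.sent_id,
                    confidence=confidence,
                    rule_id=rule_id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# rules


def extract_found_in(
    g: SentenceGraph,
    proteins: Sequence[EntityMention],
    locations: Sequence[EntityMention],
    lex: TriggerLexicon,
) -> list[Relation]:
    """Explicit localization statements (verbal, nominal or adjectival trigger)."""
    prot_heads = _by_head(p for p in proteins if p.sent_id == g.sent_id)
    loc_heads = _by_head(l for l in locations if l.sent_id == g.sent_id)
    out: list[Relation] = []
    for tm in find_triggers(g, lex, "found_in"):
        locs = _nmod_targets(g, tm.token, LOCATIVE_PREPOSITIONS, loc_heads)
        if not locs:
            continue
        prots = _protein_args(g, tm, prot_heads, labels=SUBJECT_LABELS)
        out += _emit_location(g, "found_in", f"found_in.{tm.form}", tm, prots, locs)
    return out


def extract_movement(
    g: SentenceGraph,
    proteins: Sequence[EntityMention],
    locations: Sequence[EntityMention],
    lex: TriggerLexicon,
    *,
    accept_locative_in: bool = False,
) -> list[Relation]:
    """Movement verbs: the moved protein ends up at (or leaves) the location.

    The moved entity is the object for transitives/passives and the subject
    otherwise.  Plain locative ``nmod:in`` is rejected unless
    ``accept_locative_in`` is set — movement verbs select directional
    prepositions.
    """
    prot_heads = _by_head(p for p in proteins if p.sent_id == g.sent_id)
    loc_heads = _by_head(l for l in locations if l.sent_id == g.sent_id)
    preps = list(MOVEMENT_PREPOSITIONS) + (
        list(LOCATIVE_PREPOSITIONS) if accept_locative_in else []
    )
    out: list[Relation] = []
    for tm in find_triggers(g, lex, "movement"):
        locs = _nmod_targets(g, tm.token, preps, loc_heads)
        if not locs:
            continue
        if tm.form == "nominal":
            prots = _protein_args(g, tm, prot_heads, labels=())
        else:
            moved = []
            for label in list(OBJECT_LABELS) + list(PASSIVE_SUBJECT_LABELS):
                moved += g.dependents(tm.token, label)
            if not moved:
                moved = g.dependents(tm.token, "nsubj")
            prots = _expand_to_mentions(g, moved, prot_heads)
        out += _emit_location(g, "moves", f"movement.{tm.form}", tm, prots, locs)
    return out


def extract_event_location(
    g: SentenceGraph,
    proteins: Sequence[EntityMention],
    locations: Sequence[EntityMention],
    lex: TriggerLexicon,
) -> list[Relation]:
    """Proteins participating in an event that occurred in a location.

    Every protein among the event's ``nsubj``/``dobj``/``nmod:with``
    arguments (after member-collection expansion) is inferred to be in the
    location the event carries via a locative modifier.
    """
    prot_heads = _by_head(p for p in proteins if p.sent_id == g.sent_id)
    loc_heads = _by_head(l for l in locations if l.sent_id == g.sent_id)
    out: list[Relation] = []
    for tm in find_triggers(g, lex, "event"):
        locs = _nmod_targets(g, tm.token, LOCATIVE_PREPOSITIONS, loc_heads)
        if not locs:
            continue
        prots = _protein_args(
            g,
            tm,
            prot_heads,
            labels=list(SUBJECT_LABELS) + list(OBJECT_LABELS) + ["nmod:with"],
        )
        out += _emit_location(g, "event_in", f"event_in.{tm.form}", tm, prots, locs)
    return out


def extract_staining(
    doc: Document,
    proteins_by_sentence: dict[str, Sequence[EntityMention]],
    locations_by_sentence: dict[str, Sequence[EntityMention]],
    lex: TriggerLexicon,
) -> list[Relation]:
    """Staining heuristic over a document (low confidence).

    For each sentence containing a staining trigger: if the sentence has at
    least one location mention and exactly one distinct non-tag protein is
    mentioned in the same or the immediately preceding sentence, that
    protein is inferred to be in each location.  The window is never wider.
    """
    out: list[Relation] = []
    ordered = list(doc.sentences())
    for i, g in enumerate(ordered):
        triggers = find_triggers(g, lex, "staining")
        if not triggers:
            continue
        locs = [l for l in locations_by_sentence.get(g.sent_id, ()) if l.sent_id == g.sent_id]
        if not locs:
            continue
        window = [g.sent_id] + ([ordered[i - 1].sent_id] if i > 0 else [])
        candidates: dict[str, EntityMention] = {}
        for sid in window:
            for p in proteins_by_sentence.get(sid, ()):
                if not p.is_tag:
                    candidates.setdefault(p.norm_id or p.text, p)
        if len(candidates) != 1:
            continue
        protein = next(iter(candidates.values()))
        tm = triggers[0]
        for loc in locs:
            out.append(
                Relation(
                    rtype="staining_in",
                    participants={"protein": protein, "location": loc},
                    trigger=tm,
                    sent_id=g.sent_id,
                    confidence="low",
                    rule_id="staining",
                )
            )
    return out
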