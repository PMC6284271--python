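"""Entity mentions: dictionary tagging and stand-off protein input.

Location and complex-name mentions are found by case-insensitive,
contiguous, leftmost-longest dictionary matching over token spans (surface
form first, then lemmas, so plurals still hit).  Complex *phrases* are
found syntactically: a noun whose form ends in an f-term suffix heads a
phrase made of the f-term plus its contiguous nominal premodifiers
("the Aurora B kinase complex").

Protein/gene mentions come from outside the package: gene normalization is
an upstream concern, and its output enters as stand-off rows
``(sent_id, start, end, [type,] gene_id)`` referencing character offsets.
A small naive tagger (:func:`tag_proteins_naive`) exists for demos only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, TextIO

from .depgraph import Document, SentenceGraph
from .lexicons import (
    ComplexDictionary,
    DataError,
    DEFAULT_TAGS,
    LocationDictionary,
    is_complex_fterm,
)

__all__ = [
    "EntityMention",
    "tag_locations",
    "tag_complexes",
    "read_standoff_proteins",
    "tag_proteins_naive",
]

ENTITY_TYPES = ("protein", "location", "complex_name", "complex_phrase")

#: POS tags allowed inside a nominal premodifier chain.
_NOMINAL_POS = ("NOUN", "PROPN", "ADJ", "NUM")

#: Longest dictionary entry considered, in tokens.
_MAX_SPAN = 6


@dataclass(frozen=True)
class EntityMention:
    """A typed span in one sentence.

    ``head_token`` is the token index of the syntactic head (last token of
    a dictionary span; the f-term token of a complex phrase).  ``norm_id``
    is a gene identifier for proteins, a GO ID for locations and linked
    complex names, and ``None`` for complex phrases or unlinked names.
    """

    sent_id: str
    char_start: int
    char_end: int
    head_token: int
    etype: str
    text: str
    norm_id: str | None = None
    is_tag: bool = False

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.etype!r}")
        if self.char_end <= self.char_start:
            raise ValueError(f"empty mention span in {self.sent_id}")


def _span_text(g: SentenceGraph, i: int, j: int) -> str:
    return g.text[g.tokens[i].char_start : g.tokens[j].char_end]


def _dictionary_matches(
    g: SentenceGraph, entries: dict[str, str], etype: str
) -> list[EntityMention]:
    """Leftmost-longest, non-overlapping, token-aligned dictionary matching."""
    out: list[EntityMention] = []
    n = len(g.tokens)
    i = 0
    while i < n:
        hit: tuple[int, str] | None = None
        for j in range(min(i + _MAX_SPAN, n) - 1, i - 1, -1):
            surface = _span_text(g, i, j).lower()
            key = surface
            if key not in entries:
                key = " ".join(t.lemma.lower() for t in g.tokens[i : j + 1])
            if key in entries:
                hit = (j, entries[key])
                break
        if hit is None:
            i += 1
            continue
        j, norm = hit
        out.append(
            EntityMention(
                sent_id=g.sent_id,
                char_start=g.tokens[i].char_start,
                char_end=g.tokens[j].char_end,
                head_token=g.tokens[j].index,
                etype=etype,
                text=_span_text(g, i, j),
                norm_id=norm or None,
            )
        )
        i = j + 1
    return out


def tag_locations(g: SentenceGraph, d: LocationDictionary) -> list[EntityMention]:
    """Subcellular-location mentions via dictionary lookup.

    Only nouns can anchor a location mention; location *adjectives*
    ("nuclear", "cytoplasmic") are not dictionary entries and never tagged —
    phrases like "cytoplasmic CD3" state existing knowledge, not a finding,
    and must not produce annotations.
    """
    mentions = _dictionary_matches(g, d.entries, "location")
    return [m for m in mentions if g.token(m.head_token).pos in ("NOUN", "PROPN")]


def tag_complexes(g: SentenceGraph, cd: ComplexDictionary | None = None) -> list[EntityMention]:
    """Protein-complex mentions: dictionary names plus f-term phrases.

    A dictionary match subsumes any overlapping f-term phrase, so "the
    yeast eIF3 complex" yields one ``complex_name`` mention, not an extra
    generic phrase.
    """
    named = _dictionary_matches(g, cd.entries, "complex_name") if cd else []
    taken = [(m.char_start, m.char_end) for m in named]

    phrases: list[EntityMention] = []
    for k, tok in enumerate(g.tokens):
        if tok.pos not in ("NOUN", "PROPN") or not is_complex_fterm(tok.text):
            continue
        start = k
        while start > 0 and g.tokens[start - 1].pos in _NOMINAL_POS:
            start -= 1
        cs, ce = g.tokens[start].char_start, tok.char_end
        if any(cs < e and s < ce for s, e in taken):
            continue
        phrases.append(
            EntityMention(
                sent_id=g.sent_id,
                char_start=cs,
                char_end=ce,
                head_token=tok.index,
                etype="complex_phrase",
                text=g.text[cs:ce],
            )
        )
    return sorted(named + phrases, key=lambda m: m.char_start)


def _head_token_for_span(g: SentenceGraph, start: int, end: int) -> int:
    """Last token overlapping [start, end) — English nominals are right-headed."""
    overlapping = [t for t in g.tokens if t.char_start < end and start < t.char_end]
    if not overlapping:
        raise DataError(f"{g.sent_id}: span [{start}, {end}) covers no token")
    return overlapping[-1].index


def read_standoff_proteins(
    stream: TextIO | Iterable[str],
    doc: Document,
    tags: frozenset[str] = DEFAULT_TAGS,
) -> list[EntityMention]:
    """Read stand-off protein mentions.

    Rows are tab-separated ``sent_id, start, end, gene_id`` or
    ``sent_id, start, end, type, gene_id``.  Spans out of bounds raise
    :class:`DataError` with the row number.  A mention whose surface form
    is a known tag name (GFP, FLAG, ...) is flagged ``is_tag``.
    """
    sentences = {s.sent_id: s for s in doc.sentences()}
    out: list[EntityMention] = []
    for rowno, row in enumerate(csv.reader(stream, delimiter="\t"), start=1):
        if not row or not row[0].strip() or row[0].startswith("#"):
            continue
        if len(row) not in (4, 5):
            raise DataError(f"row {rowno}: expected 4 or 5 columns, got {len(row)}")
        sent_id = row[0].strip()
        if sent_id not in sentences:
            raise DataError(f"row {rowno}: unknown sent_id {sent_id!r}")
        g = sentences[sent_id]
        try:
            start, end = int(row[1]), int(row[2])
        except ValueError as exc:
            raise DataError(f"row {rowno}: non-integer offsets") from exc
        if not (0 <= start < end <= len(g.text)):
            raise DataError(
                f"row {rowno}: span [{start}, {end}) out of bounds for {sent_id!r}"
            )
        norm_id = row[-1].strip()
        surface = g.text[start:end]
        out.append(
            EntityMention(
                sent_id=sent_id,
                char_start=start,
                char_end=end,
                head_token=_head_token_for_span(g, start, end),
                etype="protein",
                text=surface,
                norm_id=norm_id or None,
                is_tag=surface in tags,
            )
        )
    return out


def tag_proteins_naive(
    g: SentenceGraph,
    names: dict[str, str],
    tags: frozenset[str] = DEFAULT_TAGS,
) -> list[EntityMention]:
    """Demo-only protein tagger: exact token-level name lookup.

    ``names`` maps surface form to gene identifier.  Real use feeds
    normalized mentions via :func:`read_standoff_proteins` instead.
    """
    out = []
    for t in g.tokens:
        if t.text in names:
            out.append(
                EntityMention(
                    sent_id=g.sent_id,
                    char_start=t.char_start,
                    char_end=t.char_end,
                    head_token=t.index,
                    etype="protein",
                    text=t.text,
                    norm_id=names[t.text],
                    is_tag=t.text in tags,
                )
            )
    return out
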