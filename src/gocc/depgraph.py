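"""Dependency-graph data model and CoNLL-U serialization.

Every extraction rule in this package matches against a
:class:`SentenceGraph`: the sentence tokens plus labeled, directed
dependency edges between them.  The dialect is UD-style labels with
Stanford-style preposition collapsing: a prepositional modifier carries a
single edge labeled ``nmod:<prep>`` (e.g. ``nmod:in``), and coordination
carries ``conj:<cc>`` (e.g. ``conj:and``) when the coordinator is
recoverable.  :func:`read_conllu` normalizes plain UD output
(``nmod``/``obl`` + ``case``, ``conj`` + ``cc``) into that form, so graphs
from modern parsers and hand-annotated fixtures look identical to the
rules.

Rules never mutate the parse itself: they record their output as *argument
edges* (``argComponent``, ``argComplex``, ``argLocation``) in a separate
``added_edges`` set via :func:`add_argument_edge`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Protocol, Sequence, TextIO

__all__ = [
    "Token",
    "DepEdge",
    "SentenceGraph",
    "Passage",
    "Document",
    "ParserAdapter",
    "ConlluParseError",
    "StructuralError",
    "ARGUMENT_LABELS",
    "read_conllu",
    "write_conllu",
    "find_dependents",
    "add_argument_edge",
]

#: Closed vocabulary of rule-output edge labels.
ARGUMENT_LABELS = frozenset({"argComponent", "argComplex", "argLocation"})

#: UD subject labels accepted wherever a rule asks for a nominal subject.
SUBJECT_LABELS = ("nsubj", "nsubjpass", "nsubj:pass")
PASSIVE_SUBJECT_LABELS = ("nsubjpass", "nsubj:pass")
OBJECT_LABELS = ("dobj", "obj")


class ConlluParseError(ValueError):
    """Malformed CoNLL-U input; message names the offending line."""


class StructuralError(ValueError):
    """Graph violates a structural invariant (e.g. cyclic head chain)."""


@dataclass(frozen=True)
class Token:
    """One token of a sentence.

    ``index`` is 1-based (CoNLL-U convention); ``char_start``/``char_end``
    are 0-based half-open offsets into the sentence text.
    """

    index: int
    text: str
    lemma: str
    pos: str = "X"
    char_start: int = 0
    char_end: int = 0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise StructuralError(f"token index must be >= 1, got {self.index}")
        if not self.lemma:
            raise StructuralError(f"token {self.index} ({self.text!r}) has empty lemma")
        if self.char_end <= self.char_start:
            raise StructuralError(
                f"token {self.index} has empty span [{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class DepEdge:
    """Directed dependency edge from ``head`` to ``dependent`` (token indices)."""

    head: int
    dependent: int
    label: str

    def __post_init__(self) -> None:
        if self.head == self.dependent:
            raise StructuralError(f"self-loop on token {self.head} ({self.label})")
        if not self.label:
            raise StructuralError("edge label must be non-empty")


@dataclass
class SentenceGraph:
    """Tokens plus dependency edges for one sentence."""

    sent_id: str
    text: str
    tokens: tuple[Token, ...]
    edges: set[DepEdge] = field(default_factory=set)
    added_edges: set[DepEdge] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.tokens = tuple(sorted(self.tokens, key=lambda t: t.index))
        valid = {t.index for t in self.tokens}
        for e in self.edges:
            if e.head not in valid or e.dependent not in valid:
                raise StructuralError(
                    f"{self.sent_id}: edge {e} references a token outside the sentence"
                )

    # -- queries ---------------------------------------------------------

    def token(self, index: int) -> Token:
        for t in self.tokens:
            if t.index == index:
                return t
        raise IndexError(f"{self.sent_id}: no token with index {index}")

    def has_token(self, index: int) -> bool:
        return any(t.index == index for t in self.tokens)

    def dependents(self, head: int, label_pattern: str | None = None) -> list[int]:
        """Token indices governed by ``head``, ordered by position."""
        out = [
            e.dependent
            for e in self.edges
            if e.head == head and (label_pattern is None or _match(e.label, label_pattern))
        ]
        return sorted(out)

    def heads_of(self, dependent: int, label_pattern: str | None = None) -> list[int]:
        out = [
            e.head
            for e in self.edges
            if e.dependent == dependent
            and (label_pattern is None or _match(e.label, label_pattern))
        ]
        return sorted(out)

    def edge_label(self, head: int, dependent: int) -> str | None:
        for e in self.edges:
            if e.head == head and e.dependent == dependent:
                return e.label
        return None


@dataclass
class Passage:
    """A contiguous run of sentences under one section heading."""

    section: str
    sentences: list[SentenceGraph]


@dataclass
class Document:
    """An article: ordered passages, each a labeled list of sentences."""

    doc_id: str
    passages: list[Passage]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.passages:
            for s in p.sentences:
                if s.sent_id in seen:
                    raise StructuralError(
                        f"{self.doc_id}: duplicate sent_id {s.sent_id!r}"
                    )
                seen.add(s.sent_id)

    def sentences(self) -> Iterator[SentenceGraph]:
        for p in self.passages:
            yield from p.sentences

    def sentence(self, sent_id: str) -> SentenceGraph:
        for s in self.sentences():
            if s.sent_id == sent_id:
                return s
        raise KeyError(f"{self.doc_id}: no sentence {sent_id!r}")


class ParserAdapter(Protocol):
    """Contract for plugging in a live syntactic parser.

    Implementations turn raw text into one :class:`SentenceGraph` per
    sentence, with labels already in the collapsed ``nmod:<prep>`` dialect
    (or plain UD, followed by :func:`normalize_edges`).
    """

    def parse(self, text: str, doc_id: str = "doc") -> list[SentenceGraph]: ...


# ---------------------------------------------------------------------------
# label pattern matching


def _match(label: str, pattern: str) -> bool:
    """``pattern`` is ``|``-separated alternatives; a trailing ``*`` makes an
    alternative a prefix match (``nmod:*`` matches ``nmod:in``)."""
    for alt in pattern.split("|"):
        if alt.endswith("*"):
            if label.startswith(alt[:-1]):
                return True
        elif label == alt:
            return True
    return False


def find_dependents(g: SentenceGraph, head: int, label_pattern: str) -> list[int]:
    """Dependents of ``head`` whose edge label matches ``label_pattern``.

    Raises ``IndexError`` for an invalid head index.  Results are ordered by
    token index.
    """
    g.token(head)  # bounds check
    return g.dependents(head, label_pattern)


def add_argument_edge(g: SentenceGraph, trigger: int, target: int, label: str) -> SentenceGraph:
    """Record a rule-output edge (idempotent).

    ``label`` must be one of ``argComponent``/``argComplex``/``argLocation``;
    anything else is a contract violation.
    """
    if label not in ARGUMENT_LABELS:
        raise ValueError(
            f"argument label must be one of {sorted(ARGUMENT_LABELS)}, got {label!r}"
        )
    g.token(trigger)
    g.token(target)
    g.added_edges.add(DepEdge(trigger, target, label))
    return g


# ---------------------------------------------------------------------------
# normalization

_COLLAPSIBLE = {"nmod", "obl"}


def normalize_edges(tokens: Sequence[Token], edges: Iterable[DepEdge]) -> set[DepEdge]:
    """Collapse plain-UD prepositional and coordination structure.

    * ``nmod``/``obl`` (and ``obl:<x>``) edges pick up the preposition from a
      ``case`` child of the dependent: ``nmod(found, cytoplasm)`` +
      ``case(cytoplasm, in)`` becomes ``nmod:in(found, cytoplasm)``.
    * bare ``conj`` picks up the coordinator from a ``cc`` child of the
      dependent (or, failing that, of the head): ``conj:and``.  If no
      coordinator is recoverable the label stays ``conj``.

    The function is deterministic: two serializations of the same parse
    normalize to the same edge set.
    """
    edges = set(edges)
    lemma = {t.index: t.lemma.lower() for t in tokens}

    def case_child(dep: int) -> str | None:
        marks = sorted(
            e.dependent for e in edges if e.head == dep and e.label in ("case", "mark")
        )
        return lemma.get(marks[0]) if marks else None

    def cc_child(*nodes: int) -> str | None:
        for node in nodes:
            ccs = sorted(e.dependent for e in edges if e.head == node and e.label == "cc")
            if ccs:
                return lemma.get(ccs[0])
        return None

    out: set[DepEdge] = set()
    for e in edges:
        label = e.label
        base = label.split(":", 1)[0]
        if base in _COLLAPSIBLE:
            if ":" in label and base == "nmod":
                pass  # already collapsed
            else:
                prep = case_child(e.dependent)
                if ":" in label:  # obl:in -> nmod:in
                    label = "nmod:" + label.split(":", 1)[1]
                elif prep:
                    label = f"nmod:{prep}"
                else:
                    label = "nmod"
        elif label == "conj":
            cc = cc_child(e.dependent, e.head)
            if cc:
                label = f"conj:{cc}"
        out.add(DepEdge(e.head, e.dependent, label))
    return out


# ---------------------------------------------------------------------------
# CoNLL-U I/O

_ID_SKIP = re.compile(r"^\d+[-.]\d+$")  # multiword ranges / empty nodes


def read_conllu(stream: TextIO | str) -> list[SentenceGraph]:
    """Read a CoNLL-U stream into normalized :class:`SentenceGraph` objects.

    Recognizes ``# sent_id`` and ``# text`` comments; character offsets are
    recovered by scanning the sentence text left to right (or, absent a
    ``# text`` line, by joining forms with single spaces).  Raises
    :class:`ConlluParseError` naming the line for malformed token lines and
    :class:`StructuralError` for cyclic head chains.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    graphs: list[SentenceGraph] = []
    block: list[tuple[int, str]] = []
    meta: dict[str, str] = {}

    def flush(end_line: int) -> None:
        nonlocal block, meta
        if block:
            graphs.append(_build_sentence(block, meta, len(graphs)))
        block, meta = [], {}

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*=\s*(.*)", line)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        block.append((lineno, line))
    flush(len(lines) + 1)
    return graphs


def _build_sentence(
    block: list[tuple[int, str]], meta: dict[str, str], ordinal: int
) -> SentenceGraph:
    rows: list[tuple[int, str, str, str, int, str]] = []
    for lineno, line in block:
        cols = line.split("\t")
        if len(cols) == 1:
            cols = line.split()
        if len(cols) < 8:
            raise ConlluParseError(
                f"line {lineno}: expected >= 8 tab-separated columns, got {len(cols)}"
            )
        if _ID_SKIP.match(cols[0]):
            continue
        try:
            idx = int(cols[0])
            head = int(cols[6])
        except ValueError as exc:
            raise ConlluParseError(f"line {lineno}: non-integer ID or HEAD field") from exc
        form, lemma_, upos, deprel = cols[1], cols[2], cols[3], cols[7]
        if lemma_ == "_":
            lemma_ = form
        rows.append((idx, form, lemma_, upos, head, deprel))

    text = meta.get("text") or " ".join(r[1] for r in rows)
    sent_id = meta.get("sent_id") or f"s{ordinal + 1}"

    tokens: list[Token] = []
    cursor = 0
    for idx, form, lemma_, upos, _head, _dep in rows:
        start = text.find(form, cursor)
        if start < 0:
            raise ConlluParseError(
                f"sentence {sent_id!r}: token {form!r} not found in # text"
            )
        tokens.append(Token(idx, form, lemma_, upos, start, start + len(form)))
        cursor = start + len(form)

    # cycle detection over the basic head chain
    head_of = {idx: head for idx, _f, _l, _u, head, _d in rows}
    for start_idx in head_of:
        seen = set()
        node = start_idx
        while node != 0:
            if node in seen:
                raise StructuralError(
                    f"sentence {sent_id!r}: cyclic head chain through token {node}"
                )
            seen.add(node)
            node = head_of.get(node, 0)

    edges = {
        DepEdge(head, idx, deprel)
        for idx, _f, _l, _u, head, deprel in rows
        if head != 0
    }
    return SentenceGraph(sent_id, text, tuple(tokens), normalize_edges(tokens, edges))


def write_conllu(graphs: Iterable[SentenceGraph]) -> str:
    """Serialize graphs to CoNLL-U (collapsed labels stored in DEPREL).

    Only the basic head/label structure round-trips; a token with several
    incoming edges cannot be represented and raises :class:`StructuralError`.
    """
    out: list[str] = []
    for g in graphs:
        out.append(f"# sent_id = {g.sent_id}")
        out.append(f"# text = {g.text}")
        incoming: dict[int, DepEdge] = {}
        for e in g.edges:
            if e.dependent in incoming:
                raise StructuralError(
                    f"{g.sent_id}: token {e.dependent} has multiple heads; "
                    "cannot serialize to CoNLL-U"
                )
            incoming[e.dependent] = e
        for t in g.tokens:
            e = incoming.get(t.index)
            head, label = (e.head, e.label) if e else (0, "root")
            out.append(
                "\t".join(
                    [str(t.index), t.text, t.lemma, t.pos, "_", "_", str(head), label, "_", "_"]
                )
            )
        out.append("")
    return "\n".join(out) + "\n"
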