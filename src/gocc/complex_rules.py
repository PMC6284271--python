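"""Protein-complex membership extraction.

Three rule groups:

* **part-whole** — a protein is stated to be part of a complex, in one of
  three argument configurations: (1) predicate nominal "P is a subunit of
  C"; (2) containment verb "C contains/consists of P" with
  member-collection expansion on the object; (3) passive detection "P was
  detected in C".
* **formation** — proteins form a complex: "form" (or similar) with an
  f-term object ("A, B and C form a trimer"), a verb whose lemma is itself
  an f-term base ("Mad1 dimerizes with Max", "X complexes with Y"), or a
  nominal trigger ("dimerization of A and B").
* **PPI + promotion** — generic protein–protein interactions ("interact",
  "bind", "associate") are extracted first, then *promoted* to complex
  co-membership only when the text indicates the interaction (a) is stable,
  (b) performs some function (the trigger is conjoined to, or governs a
  purpose clause containing, another verb), or (c) involves more than two
  components.  Unnamed participants ("... with several other proteins", a
  complex phrase partner) count toward the more-than-two threshold, but
  only named proteins receive annotations.
"""

from __future__ import annotations

from typing import Sequence

from .depgraph import (
    OBJECT_LABELS,
    PASSIVE_SUBJECT_LABELS,
    SUBJECT_LABELS,
    SentenceGraph,
    add_argument_edge,
)
from .entities import EntityMention
from .lexicons import TriggerLexicon, is_complex_fterm
from .location_rules import (
    PromotionEvidence,
    Relation,
    TriggerMatch,
    find_triggers,
    _by_head,
    _expand_to_mentions,
    _nmod_targets,
)
from .propagation import expand_member_collection, resolve_copular

__all__ = [
    "extract_part_whole",
    "extract_formation",
    "extract_ppi",
    "promote_ppi",
    "is_fterm_verb",
]

_PPI_ARG_LABELS = tuple(SUBJECT_LABELS) + tuple(OBJECT_LABELS) + ("nmod:with", "nmod:to")

_COMPLEX_TYPES = ("complex_name", "complex_phrase")


def is_fterm_verb(lemma: str) -> bool:
    """True for verbs whose lemma is an f-term base: "complex" (as in
    "complexes with"), "dimerize", "oligomerize", ..."""
    lemma = lemma.lower()
    if is_complex_fterm(lemma):
        return True
    for suffix in ("ize", "ise"):
        if lemma.endswith(suffix) and is_complex_fterm(lemma[: -len(suffix)]):
            return True
    return False


def _part_of(
    g: SentenceGraph,
    tm: TriggerMatch,
    protein: EntityMention,
    complex_m: EntityMention,
    rule_id: str,
    promotion: PromotionEvidence | None = None,
) -> Relation:
    add_argument_edge(g, tm.token, protein.head_token, "argComponent")
    add_argument_edge(g, tm.token, complex_m.head_token, "argComplex")
    return Relation(
        rtype="part_of_complex",
        participants={"protein": protein, "complex": complex_m},
        trigger=tm,
        sent_id=g.sent_id,
        rule_id=rule_id,
        promotion=promotion,
    )


def _component_pair(
    g: SentenceGraph,
    tm: TriggerMatch,
    a: EntityMention,
    b: EntityMention,
    rule_id: str,
    rtype: str = "component_component",
    promotion: PromotionEvidence | None = None,
) -> Relation:
    first, second = sorted((a, b), key=lambda m: (m.char_start, m.text))
    add_argument_edge(g, tm.token, first.head_token, "argComponent")
    add_argument_edge(g, tm.token, second.head_token, "argComponent")
    return Relation(
        rtype=rtype,
        participants={"protein": first, "protein2": second},
        trigger=tm,
        sent_id=g.sent_id,
        rule_id=rule_id,
        promotion=promotion,
    )


# ---------------------------------------------------------------------------
# part-whole


def extract_part_whole(
    g: SentenceGraph,
    proteins: Sequence[EntityMention],
    complexes: Sequence[EntityMention],
    lex: TriggerLexicon,
) -> list[Relation]:
    """The three part-whole configurations (see module docstring)."""
    prot_heads = _by_head(p for p in proteins if p.sent_id == g.sent_id)
    cx_heads = _by_head(c for c in complexes if c.sent_id == g.sent_id)
    out: list[Relation] = []

    # Type 1: "P is a subunit/component of C" — protein is the copular
    # subject, complex the nmod:of argument of the trigger noun.
    for tm in find_triggers(g, lex, "part_whole_noun"):
        if tm.form != "nominal":
            continue
        cx = _nmod_targets(g, tm.token, ("of",), cx_heads)
        if not cx:
            continue
        subj_tokens = list(g.dependents(tm.token, "|".join(SUBJECT_LABELS)))
        resolved = resolve_copular(g, tm.token)
        if resolved != tm.token:
            subj_tokens.append(resolved)
        prots = _expand_to_mentions(g, subj_tokens, prot_heads)
        for p in prots:
            for c in cx:
                out.append(_part_of(g, tm, p, c, "part_whole.type1"))

    # Type 2: "C contains P" / "C consists of P" — complex subject,
    # protein object, with member-collection expansion on the object.
    for tm in find_triggers(g, lex, "containment_verb"):
        if tm.form != "verbal":
            continue
        subj = _expand_to_mentions(g, g.dependents(tm.token, "nsubj"), cx_heads)
        if not subj:
            continue
        obj_tokens = []
        for label in OBJECT_LABELS:
            obj_tokens += g.dependents(tm.token, label)
        lemma = g.token(tm.token).lemma.lower()
        if lemma in ("consist", "comprise"):
            obj_tokens += g.dependents(tm.token, "nmod:of")
        prots = _expand_to_mentions(g, obj_tokens, prot_heads)
        for c in subj:
            for p in prots:
                out.append(_part_of(g, tm, p, c, "part_whole.type2"))

    # Type 3: "P was detected in C" — passive subject protein, complex
    # via nmod:in.  Hyphenated triggers ("detected-in") arrive from parsers
    # as the verb plus a case-marked modifier, which is what this matches.
    for tm in find_triggers(g, lex, "detected_in"):
        if tm.form != "verbal":
            continue
        cx = _nmod_targets(g, tm.token, ("in",), cx_heads)
        if not cx:
            continue
        prots = _expand_to_mentions(
            g, g.dependents(tm.token, "|".join(PASSIVE_SUBJECT_LABELS)), prot_heads
        )
        for p in prots:
            for c in cx:
                out.append(_part_of(g, tm, p, c, "part_whole.type3"))

    return out


# ---------------------------------------------------------------------------
# formation


def extract_formation(
    g: SentenceGraph,
    proteins: Sequence[EntityMention],
    complexes: Sequence[EntityMention],
    lex: TriggerLexicon,
) -> list[Relation]:
    """Complex-formation statements (see module docstring)."""
    prot_heads = _by_head(p for p in proteins if p.sent_id == g.sent_id)
    cx_heads = _by_head(c for c in complexes if c.sent_id == g.sent_id)
    out: list[Relation] = []

    for tm in find_triggers(g, lex, "formation"):
        lemma = g.token(tm.token).lemma.lower()

        if tm.form == "verbal" and is_fterm_verb(lemma):
            # "Mad1 dimerizes with Max", "X complexes with Y"
            subs = _expand_to_mentions(g, g.dependents(tm.token, "nsubj"), prot_heads)
            partners = _nmod_targets(g, tm.token, ("with",), prot_heads)
            for a in subs:
                for b in partners:
                    if a is not b:
                        out.append(_component_pair(g, tm, a, b, "formation.fterm_verb"))
            continue

        if tm.form == "verbal":
            # "A, B and C form a (stable) trimer" — the object must be an
            # f-term complex phrase; subjects are expanded and paired.
            targets = []
            for label in OBJECT_LABELS:
                for dep in g.dependents(tm.token, label):
                    if dep in cx_heads:
                        targets.append(cx_heads[dep])
            if not targets:
                continue
            subs = _expand_to_mentions(
                g,
                g.dependents(tm.token, "|".join(SUBJECT_LABELS)),
                prot_heads,
            )
            for i, a in enumerate(subs):
                for b in subs[i + 1 :]:
                    out.append(_component_pair(g, tm, a, b, "formation.form"))
            for p in subs:
                for c in targets:
                    out.append(_part_of(g, tm, p, c, "formation.form"))
            continue

        if tm.form == "nominal":
            # "formation/dimerization of A and B"
            args = []
            for prep in ("of", "between", "with"):
                args += _nmod_targets(g, tm.token, (prep,), prot_heads)
            uniq: list[EntityMention] = []
            for m in args:
                if m not in uniq:
                    uniq.append(m)
            for i, a in enumerate(uniq):
                for b in uniq[i + 1 :]:
                    out.append(_component_pair(g, tm, a, b, "formation.nominal"))
    return out


# ---------------------------------------------------------------------------
# PPI and promotion


def extract_ppi(
    g: SentenceGraph,
    proteins: Sequence[EntityMention],
    lex: TriggerLexicon,
    complexes: Sequence[EntityMention] = (),
) -> list[Relation]:
    """Protein–protein interactions: one ``ppi`` relation per unordered pair.

    All proteins among the trigger's subject/object/``nmod:with``/``nmod:to``
    arguments (member-collection expanded) participate; with n proteins all
    n·(n−1)/2 pairs are emitted.  When only one protein is named but a
    complex mention is a partner, a single ``ppi`` relation with roles
    ``protein``/``complex`` is emitted so promotion can still apply.
    """
    prot_heads = _by_head(p for p in proteins if p.sent_id == g.sent_id)
    cx_heads = _by_head(c for c in complexes if c.sent_id == g.sent_id)
    out: list[Relation] = []
    for tm in find_triggers(g, lex, "ppi"):
        if tm.form != "verbal":
            continue
        arg_tokens = []
        for label in _PPI_ARG_LABELS:
            arg_tokens += g.dependents(tm.token, label)
        participants = _expand_to_mentions(g, arg_tokens, prot_heads)
        cx_partners = _expand_to_mentions(g, arg_tokens, cx_heads)
        for i, a in enumerate(participants):
            for b in participants[i + 1 :]:
                out.append(_component_pair(g, tm, a, b, "ppi", rtype="ppi"))
        if len(participants) == 1 and cx_partners:
            for c in cx_partners:
                out.append(
                    Relation(
                        rtype="ppi",
                        participants={"protein": participants[0], "complex": c},
                        trigger=tm,
                        sent_id=g.sent_id,
                        rule_id="ppi",
                    )
                )
    return out


def _stability_evidence(g: SentenceGraph, trigger: int, lex: TriggerLexicon) -> int | None:
    """Token index of a stability marker modifying the trigger's clause."""
    candidates = g.dependents(trigger, "advmod|amod")
    for label in OBJECT_LABELS + ("nmod:with",):
        for dep in g.dependents(trigger, label):
            candidates += g.dependents(dep, "amod")
    for tok in sorted(candidates):
        if lex.matches(g.token(tok), "stability_marker"):
            return tok
    return None


def _function_evidence(g: SentenceGraph, trigger: int) -> int | None:
    """A conjoined verb or a purpose clause governed by the PPI trigger."""
    for dep in g.dependents(trigger, "conj|conj:*"):
        if g.token(dep).pos in ("VERB", "AUX"):
            return dep
    for dep in g.dependents(trigger, "xcomp|advcl|advcl:*"):
        if g.token(dep).pos in ("VERB", "AUX"):
            return dep
    return None


def promote_ppi(
    g: SentenceGraph,
    ppi_relations: Sequence[Relation],
    lex: TriggerLexicon,
    proteins: Sequence[EntityMention] = (),
    complexes: Sequence[EntityMention] = (),
) -> list[Relation]:
    """Promote PPIs to complex co-membership when the heuristic holds.

    Promotion never invents pairs: every promoted ``component_component``
    pair occurs among the input ``ppi`` relations, and the complex-partner
    case yields ``part_of_complex`` for the named protein only.  A
    complex-phrase partner counts as two components (a complex has at least
    two), so a named protein interacting with a complex clears the
    more-than-two threshold.
    """
    prot_heads = {m.head_token for m in proteins}
    groups: dict[int, list[Relation]] = {}
    for r in ppi_relations:
        if r.rtype == "ppi" and r.sent_id == g.sent_id:
            groups.setdefault(r.trigger.token, []).append(r)

    out: list[Relation] = []
    for trig_tok in sorted(groups):
        rels = groups[trig_tok]
        tm = rels[0].trigger
        named: dict[int, EntityMention] = {}
        cx_partners: dict[int, EntityMention] = {}
        for r in rels:
            for role, m in r.participants.items():
                if m.etype == "protein":
                    named[m.head_token] = m
                elif m.etype in _COMPLEX_TYPES:
                    cx_partners[m.head_token] = m
        if not prot_heads:
            prot_heads = set(named)

        # unnamed nominal participants count toward the >2 threshold
        arg_tokens: list[int] = []
        for label in _PPI_ARG_LABELS:
            arg_tokens += g.dependents(trig_tok, label)
        expanded: set[int] = set()
        for t in arg_tokens:
            expanded.update(expand_member_collection(g, t))
        unnamed = sum(
            1
            for t in sorted(expanded)
            if t not in prot_heads
            and t not in cx_partners
            and g.token(t).pos in ("NOUN", "PROPN")
        )
        total = len(named) + unnamed + 2 * len(cx_partners)

        evidence: PromotionEvidence | None = None
        stable = _stability_evidence(g, trig_tok, lex)
        if stable is not None:
            evidence = PromotionEvidence("stable", stable)
        else:
            func = _function_evidence(g, trig_tok)
            if func is not None:
                evidence = PromotionEvidence("function", func)
            elif total > 2:
                evidence = PromotionEvidence("multi_component", total)
        if evidence is None:
            continue

        emitted: set[tuple] = set()
        for r in rels:
            a, b = r.participants.get("protein"), r.participants.get("protein2")
            if a is not None and b is not None:
                key = tuple(sorted((a.head_token, b.head_token)))
                if key not in emitted:
                    emitted.add(key)
                    out.append(
                        _component_pair(
                            g, tm, a, b, f"ppi_promotion.{evidence.basis}",
                            promotion=evidence,
                        )
                    )
        for cxm in cx_partners.values():
            for pm in named.values():
                out.append(
                    _part_of(
                        g, tm, pm, cxm, f"ppi_promotion.{evidence.basis}",
                        promotion=evidence,
                    )
                )
    return out
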