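"""Extra-syntactic propagation: member-collection and copular structure.

A relation stated on a collection noun ("...contains five core components:
Rpg1, Nip1, Prt1, Tif34, and Tif35") holds of each enumerated member, and a
relation stated on a predicate nominal ("CSC-1 is a subunit ...") holds of
the copular subject.  The rule modules call these helpers so individual
rules stay blind to enumeration and copula syntax.
"""

from __future__ import annotations

from .depgraph import SentenceGraph

__all__ = ["expand_member_collection", "resolve_copular", "conjunct_closure"]

#: Labels that attach enumerated members to a collection noun.  The colon
#: enumeration typically parses as ``appos`` or bare ``dep``; ``list`` covers
#: parsers that use the UD list relation.
_ENUM_LABELS = ("appos", "dep", "list")

_NOMINAL_POS = ("NOUN", "PROPN", "NUM", "X")


def conjunct_closure(g: SentenceGraph, node: int) -> list[int]:
    """``node`` plus everything reachable through ``conj``/``conj:<cc>`` edges."""
    seen = {node}
    frontier = [node]
    while frontier:
        current = frontier.pop()
        for dep in g.dependents(current, "conj|conj:*"):
            if dep not in seen:
                seen.add(dep)
                frontier.append(dep)
    return sorted(seen)


def expand_member_collection(g: SentenceGraph, node: int) -> list[int]:
    """Member token indices if ``node`` heads a collection, else ``[node]``.

    Two structures count as collections:

    * a noun governing an enumeration (``appos``/``dep``/``list`` to a
      nominal), whose members are the enumerated heads plus their conjuncts —
      the collection noun itself is never among the members;
    * a bare conjunct chain, whose members are the node and its conjuncts.

    Expansion is idempotent at the set level: expanding every returned
    member again yields a subset of the original result.
    """
    g.token(node)
    enum_heads: list[int] = []
    for label in _ENUM_LABELS:
        for dep in g.dependents(node, label):
            if g.token(dep).pos in _NOMINAL_POS:
                enum_heads.append(dep)
    if enum_heads:
        members: set[int] = set()
        for h in enum_heads:
            members.update(conjunct_closure(g, h))
        members.discard(node)
        return sorted(members)

    chain = conjunct_closure(g, node)
    return chain if len(chain) > 1 else [node]


def resolve_copular(g: SentenceGraph, predicate_head: int) -> int:
    """Subject of a copular clause headed by ``predicate_head``, else itself.

    In UD a predicate nominal/adjective governs both the copula (``cop``)
    and the subject (``nsubj``): "CSC-1 is a subunit" has
    ``cop(subunit, is)`` and ``nsubj(subunit, CSC-1)``; the resolved
    argument is CSC-1.
    """
    if g.dependents(predicate_head, "cop"):
        subjects = g.dependents(predicate_head, "nsubj|nsubj:pass|nsubjpass")
        if subjects:
            return subjects[0]
    return predicate_head
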