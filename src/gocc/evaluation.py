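"""Triplet-level evaluation against a gold standard.

Gold annotations arrive as a BioC XML collection whose annotation infons
carry a gene identifier and a GO identifier; predictions and gold are
compared as exact (doc, gene, GO-ID) triplets with standard precision
P = TP/(TP+FP), recall R = TP/(TP+FN) and F1 = 2PR/(P+R).

An optional Cellular-Component filter restricts gold triplets to the CC
domain: membership in the closure of the 19 subcellular-location roots
plus the closure of the protein-complex sub-hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, TextIO

import obonet
from lxml import etree

from .lexicons import (
    GO_ID_RE,
    GO_PROTEIN_COMPLEX,
    SUBCELLULAR_ROOTS,
    descendant_closure,
)

__all__ = ["EvaluationResult", "Triplet", "read_gold", "score", "cc_domain_ids"]

logger = logging.getLogger(__name__)

Triplet = tuple[str, str, str]  # (doc_id, gene_id, go_id)

#: Infon keys probed (case-insensitively) for the gene and GO identifiers.
DEFAULT_GENE_KEYS = ("gene_id", "geneid", "gene", "ncbi_gene_id", "entrez_id")
DEFAULT_GO_KEYS = ("go_id", "goid", "go-term", "go_term", "go")


@dataclass(frozen=True)
class EvaluationResult:
    """Counts and derived metrics; undefined ratios are reported as 0.0
    with the corresponding ``*_defined`` flag cleared."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True


def cc_domain_ids(
    obo: TextIO | str,
    location_roots: Iterable[str] | None = None,
    complex_root: str = GO_PROTEIN_COMPLEX,
) -> set[str]:
    """GO IDs in the CC domain: location-root closures ∪ complex closure."""
    graph = obonet.read_obo(obo)
    roots = list(location_roots) if location_roots is not None else list(SUBCELLULAR_ROOTS)
    ids: set[str] = set()
    for root in roots + [complex_root]:
        if root in graph:
            ids |= descendant_closure(graph, root)
    return ids


def read_gold(
    stream: TextIO | bytes | str,
    *,
    gene_keys: tuple[str, ...] = DEFAULT_GENE_KEYS,
    go_keys: tuple[str, ...] = DEFAULT_GO_KEYS,
    cc_terms: set[str] | None = None,
) -> set[Triplet]:
    """Extract (doc, gene, GO) triplets from a BioC XML collection.

    Annotations missing either identifier are skipped (counted in a debug
    log); malformed XML raises ``lxml.etree.XMLSyntaxError``.  With
    ``cc_terms`` given, only triplets whose GO ID is in that set are kept.
    """
    if isinstance(stream, str):
        data = stream.encode()
    elif isinstance(stream, bytes):
        data = stream
    else:
        raw = stream.read()
        data = raw.encode() if isinstance(raw, str) else raw
    root = etree.fromstring(data)

    gene_keys_l = tuple(k.lower() for k in gene_keys)
    go_keys_l = tuple(k.lower() for k in go_keys)
    triplets: set[Triplet] = set()
    skipped = 0
    for doc in root.iter("document"):
        doc_id_el = doc.find("id")
        doc_id = (doc_id_el.text or "").strip() if doc_id_el is not None else ""
        for ann in doc.iter("annotation"):
            infons = {
                (el.get("key") or "").lower(): (el.text or "").strip()
                for el in ann.findall("infon")
            }
            gene = next((infons[k] for k in gene_keys_l if infons.get(k)), None)
            go = next((infons[k] for k in go_keys_l if infons.get(k)), None)
            if not gene or not go or not GO_ID_RE.match(go):
                skipped += 1
                continue
            if cc_terms is not None and go not in cc_terms:
                continue
            triplets.add((doc_id, gene, go))
    if skipped:
        logger.warning("read_gold: skipped %d annotations missing gene/GO infons", skipped)
    return triplets


def score(predicted: set[Triplet], gold: set[Triplet]) -> EvaluationResult:
    """Exact-match triplet comparison.

    Empty prediction sets make precision undefined (reported 0.0, flagged);
    empty gold sets do the same for recall.
    """
    predicted, gold = set(predicted), set(gold)
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    p_def, r_def = tp + fp > 0, tp + fn > 0
    precision = tp / (tp + fp) if p_def else 0.0
    recall = tp / (tp + fn) if r_def else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvaluationResult(tp, fp, fn, precision, recall, f1, p_def, r_def)
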