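"""Transcription-factor regulatory models and coregulation closure.

A record links a transcription factor (TF) to the genes that express it
(``corresponds_to``) and the genes it regulates (``regulates``).  Because
many regulated genes themselves express TFs, the induced gene-gene network
is recursive and often cyclic.

Two inferred relations describe a TF's sphere of influence:

* ``coregulates`` — gene g1 expresses a TF that regulates g2;
* ``indirectly_coregulates`` — g1 reaches gk over a coregulates path of
  length >= 2 (full reachability by default; an exact two-step variant is
  available for the strict single-chain reading).

:func:`entail_tf` materializes both to fixpoint with plain forward chaining,
which coincides with DL property-chain entailment on these rules.
"""

from __future__ import annotations

import csv
import io
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple, Union
from urllib.parse import quote

from rdflib import Graph, URIRef

from .observation_store import refseq_uri
from .rdf_core import K, Vocabulary, make_vocabulary

__all__ = ["TfRecord", "TfTableError", "parse_tf_table", "tf_iri", "tf_to_rdf", "entail_tf"]


class TfTableError(ValueError):
    """A TF table row cannot be interpreted; the message names the line."""


@dataclass
class TfRecord:
    """A transcription factor, the genes expressing it, and its targets."""

    tf_id: str
    expressing_genes: Set[str] = field(default_factory=set)
    regulated_genes: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.tf_id:
            raise ValueError("tf_id must be non-empty")


_ROLES = {"expresses", "regulates"}


def parse_tf_table(stream: Union[str, io.TextIOBase]) -> List[TfRecord]:
    """Read a TF table (header ``tf_id<TAB>role<TAB>refseq``).

    Roles are ``expresses`` (the gene expresses the TF) and ``regulates``
    (the TF regulates the gene); rows aggregate per TF with set semantics.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        return []
    if [h.strip() for h in header[:3]] != ["tf_id", "role", "refseq"]:
        raise TfTableError(f"line 1: expected header tf_id<TAB>role<TAB>refseq, got {header!r}")
    records: Dict[str, TfRecord] = {}
    order: List[str] = []
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 3:
            raise TfTableError(f"line {lineno}: expected 3 columns, got {len(row)}")
        tf_id, role, acc = row[0], row[1].strip(), row[2].strip()
        if role not in _ROLES:
            raise TfTableError(f"line {lineno}: unknown role {role!r}; expected 'expresses' or 'regulates'")
        if tf_id not in records:
            records[tf_id] = TfRecord(tf_id=tf_id)
            order.append(tf_id)
        if role == "expresses":
            records[tf_id].expressing_genes.add(acc)
        else:
            records[tf_id].regulated_genes.add(acc)
    return [records[t] for t in order]


def tf_iri(tf_id: str) -> URIRef:
    """IRI for a TF in the k: namespace; ids like ``V$HEN1_01`` are
    percent-encoded so they survive IRI syntax."""
    if not tf_id:
        raise ValueError("empty TF identifier")
    return URIRef(K + quote(tf_id, safe=""))


def tf_to_rdf(records: Iterable[TfRecord], vocab: Vocabulary | None = None) -> Graph:
    """Assert the directly stated TF relations.

    ``corresponds_to`` is materialized in both directions (TF -> gene and
    gene -> TF): the inference chain composes it TF-first while the
    case-study query binds it gene-first, and with both present each holds.
    ``regulates`` is stored TF -> gene.  Gene nodes are typed as transcripts.
    """
    vocab = vocab or make_vocabulary()
    g = Graph()
    seen_genes: Set[str] = set()

    def gene_node(acc: str) -> URIRef:
        node = refseq_uri(acc)
        if acc not in seen_genes:
            seen_genes.add(acc)
            g.add((node, vocab.rdf_type, vocab.transcript_class))
        return node

    for rec in records:
        tf = tf_iri(rec.tf_id)
        for acc in rec.expressing_genes:
            gene = gene_node(acc)
            g.add((tf, vocab.corresponds_to, gene))
            g.add((gene, vocab.corresponds_to, tf))
        for acc in rec.regulated_genes:
            g.add((tf, vocab.regulates, gene_node(acc)))
    return g


def entail_tf(
    graph: Graph,
    vocab: Vocabulary | None = None,
    allow_self: bool = True,
    indirect_depth: Union[int, str] = "inf",
) -> Graph:
    """Materialize the coregulation closure.

    ``coregulates``: for every node with both corresponds_to and regulates
    assertions (i.e. every TF), each expressing gene coregulates each
    regulated gene.  ``indirectly_coregulates``: pairs joined by a
    coregulates walk of length >= 2 when ``indirect_depth`` is ``"inf"``
    (the full sphere of influence), or exactly 2 when it is ``2``.

    With ``allow_self=False``, reflexive edges (g, ., g) — which genuinely
    arise from cycles and autoregulation under the entailment semantics —
    are suppressed in the output.  The result is a superset of the input
    (minus nothing) and the operation is idempotent.
    """
    vocab = vocab or make_vocabulary()
    if indirect_depth not in (2, "2", "inf"):
        raise ValueError(f"indirect_depth must be 2 or 'inf', got {indirect_depth!r}")
    exact_two = indirect_depth in (2, "2")

    expressing: Dict[URIRef, Set[URIRef]] = defaultdict(set)
    regulated: Dict[URIRef, Set[URIRef]] = defaultdict(set)
    for s, o in graph.subject_objects(vocab.corresponds_to):
        expressing[s].add(o)
    for s, o in graph.subject_objects(vocab.regulates):
        regulated[s].add(o)

    # Rule (a): only subjects carrying regulates assertions (TF nodes) fire;
    # the gene->TF corresponds_to direction joins with nothing.
    coreg: Dict[URIRef, Set[URIRef]] = defaultdict(set)
    for tf, targets in regulated.items():
        for g1 in expressing.get(tf, ()):
            coreg[g1].update(targets)
    # Pre-existing coregulates triples participate too (idempotence on
    # already-entailed graphs).
    for s, o in graph.subject_objects(vocab.coregulates):
        coreg[s].add(o)

    # Rule (b): walks of length >= 2 (or exactly 2) over coregulates.
    reach_cache: Dict[URIRef, Set[URIRef]] = {}

    def reach_ge1(start: URIRef) -> Set[URIRef]:
        if start in reach_cache:
            return reach_cache[start]
        seen: Set[URIRef] = set()
        frontier = list(coreg.get(start, ()))
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(coreg.get(node, ()))
        reach_cache[start] = seen
        return seen

    indirect: Dict[URIRef, Set[URIRef]] = defaultdict(set)
    for g1, mids in coreg.items():
        acc = indirect[g1]
        for mid in mids:
            if exact_two:
                acc.update(coreg.get(mid, ()))
            else:
                acc.update(reach_ge1(mid))

    out = Graph()
    for triple in graph:
        out.add(triple)
    for g1, targets in coreg.items():
        for g2 in targets:
            if g1 == g2 and not allow_self:
                continue
            out.add((g1, vocab.coregulates, g2))
    for g1, targets in indirect.items():
        for g2 in targets:
            if g1 == g2 and not allow_self:
                continue
            out.add((g1, vocab.indirectly_coregulates, g2))
    if not allow_self:
        # Drop reflexive edges that may have been present in the input.
        for p in (vocab.coregulates, vocab.indirectly_coregulates):
            for s, o in list(out.subject_objects(p)):
                if s == o:
                    out.remove((s, p, o))
    return out
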