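"""GO annotation semantics: OBO parsing, SKOS conversion and propagation.

GO terms become SKOS ``Concept`` instances whose ``is_a`` hierarchy is
expressed as instance-level ``skos:broader`` edges.  Genes (as Bio2RDF
RefSeq transcripts) are linked to terms with one of three relations chosen
by annotation aspect: *participates in* (biological process), *has function*
(molecular function) and *part of* (cellular component).

The scientific payload is :func:`entail_go`: the property-chain rule

    if (gene, p, term) and (term, broader, parent) then (gene, p, parent)

applied to fixpoint for each of the three relations, so every annotation
propagates to all ancestors of its term (the true-path rule).  Forward
chaining over these Horn rules is semantically equivalent to running a DL
reasoner over the corresponding OWL 2 property-chain axioms.
"""

from __future__ import annotations

import csv
import io
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple, Union

import networkx as nx
import obonet
from rdflib import Graph, URIRef

from .observation_store import refseq_uri
from .rdf_core import GO_NS, Vocabulary, make_vocabulary

__all__ = [
    "OboTerm",
    "ConceptScheme",
    "GafRecord",
    "CyclicHierarchyError",
    "parse_obo",
    "go_term_iri",
    "to_skos",
    "aspect_property",
    "parse_gaf",
    "parse_symbol_map",
    "annotations_to_rdf",
    "entail_go",
    "ancestors",
    "ANNOTATION_PROPERTIES",
]

logger = logging.getLogger(__name__)


class CyclicHierarchyError(ValueError):
    """The is_a hierarchy contains a cycle; the message lists one."""


@dataclass(frozen=True)
class OboTerm:
    id: str
    name: str
    namespace: str
    is_a_parents: FrozenSet[str] = frozenset()
    obsolete: bool = False


@dataclass
class ConceptScheme:
    """GO terms plus their broader (child -> parent) hierarchy, a DAG."""

    terms: Dict[str, OboTerm]
    broader_edges: FrozenSet[Tuple[str, str]]

    def __post_init__(self) -> None:
        dangling = [e for e in self.broader_edges if e[0] not in self.terms or e[1] not in self.terms]
        if dangling:
            raise ValueError(f"broader edge references unknown term: {dangling[0]}")


def parse_obo(stream: Union[str, io.TextIOBase]) -> ConceptScheme:
    """Parse an OBO 1.2 flat file into a concept scheme.

    Obsolete terms are excluded; only ``is_a`` lines become broader edges
    (term-term ``part_of``/``regulates`` relationships are ignored).  A
    cyclic hierarchy raises :class:`CyclicHierarchyError` listing one cycle.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    net = obonet.read_obo(stream, ignore_obsolete=True)
    terms: Dict[str, OboTerm] = {}
    edges: Set[Tuple[str, str]] = set()
    for node, data in net.nodes(data=True):
        parents = frozenset(
            parent for _, parent, key in net.out_edges(node, keys=True) if key == "is_a"
        )
        terms[node] = OboTerm(
            id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            is_a_parents=parents,
        )
    for child, term in terms.items():
        for parent in term.is_a_parents:
            if parent in terms:
                edges.add((child, parent))
    dag = nx.DiGraph(edges)
    try:
        cycle = nx.find_cycle(dag)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join([cycle[0][0]] + [v for _, v in cycle])
        raise CyclicHierarchyError(f"cyclic is_a hierarchy: {path}")
    return ConceptScheme(terms=terms, broader_edges=frozenset(edges))


def go_term_iri(go_id: str) -> URIRef:
    """IRI for a GO accession in the legacy OBO-in-OWL dialect.

    ``GO:0006915`` -> ``http://purl.org/obo/owl/GO#GO_0006915``; this is the
    dialect the stored case-study queries use, so they run unmodified.
    """
    return URIRef(GO_NS + go_id.replace(":", "_"))


def to_skos(scheme: ConceptScheme, vocab: Vocabulary | None = None) -> Graph:
    """Express the scheme as SKOS: one ``Concept``-typed node per term and one
    ``skos:broader`` triple per is_a edge."""
    vocab = vocab or make_vocabulary()
    g = Graph()
    for term_id in scheme.terms:
        g.add((go_term_iri(term_id), vocab.rdf_type, vocab.concept))
    for child, parent in scheme.broader_edges:
        g.add((go_term_iri(child), vocab.broader, go_term_iri(parent)))
    return g


def aspect_property(aspect: str, vocab: Vocabulary | None = None) -> URIRef:
    """Annotation relation for a GAF aspect: P -> participates_in,
    F -> has_function, C -> part_of."""
    vocab = vocab or make_vocabulary()
    mapping = {"P": vocab.participates_in, "F": vocab.has_function, "C": vocab.part_of}
    try:
        return mapping[aspect]
    except KeyError:
        raise ValueError(f"unknown GAF aspect {aspect!r}; expected P, F or C") from None


@dataclass(frozen=True)
class GafRecord:
    symbol: str
    go_id: str
    aspect: str
    evidence_code: str = "IEA"
    qualifier: str = ""

    def __post_init__(self) -> None:
        if self.aspect not in {"P", "F", "C"}:
            raise ValueError(f"aspect must be P, F or C, got {self.aspect!r}")


def parse_gaf(stream: Union[str, io.TextIOBase]) -> List[GafRecord]:
    """Read a GAF 2.x file (tab-separated, ``!`` comment lines).

    Only the symbol (col 3), qualifier (col 4), GO id (col 5), evidence code
    (col 7) and aspect (col 9) are interpreted.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: List[GafRecord] = []
    for row in csv.reader(stream, delimiter="\t"):
        if not row or row[0].startswith("!"):
            continue
        if len(row) < 9:
            raise ValueError(f"GAF row with {len(row)} column(s); at least 9 required: {row!r}")
        records.append(
            GafRecord(
                symbol=row[2],
                qualifier=row[3],
                go_id=row[4],
                evidence_code=row[6],
                aspect=row[8],
            )
        )
    return records


def parse_symbol_map(stream: Union[str, io.TextIOBase]) -> Dict[str, Set[str]]:
    """Read a symbol -> RefSeq mapping table (symbol<TAB>accession per row)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    mapping: Dict[str, Set[str]] = defaultdict(set)
    for lineno, row in enumerate(csv.reader(stream, delimiter="\t"), start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2 or not row[1].strip():
            raise ValueError(f"line {lineno}: expected symbol<TAB>refseq")
        mapping[row[0]].add(row[1].strip())
    return dict(mapping)


def annotations_to_rdf(
    records: Iterable[GafRecord],
    symbol_map: Mapping[str, Set[str]],
    scheme: ConceptScheme,
    vocab: Vocabulary | None = None,
) -> Graph:
    """Cast GAF annotations as RDF over Bio2RDF transcript IRIs.

    NOT-qualified records contribute nothing.  Records whose symbol has no
    RefSeq mapping or whose term is absent from the scheme (e.g. obsolete)
    are skipped and counted in a single summary log line.  One-to-many
    symbol mappings expand to every mapped accession.
    """
    vocab = vocab or make_vocabulary()
    g = Graph()
    skipped_unmapped = 0
    skipped_unknown_term = 0
    for rec in records:
        if "NOT" in rec.qualifier.split("|"):
            continue
        if rec.go_id not in scheme.terms:
            skipped_unknown_term += 1
            continue
        accessions = symbol_map.get(rec.symbol)
        if not accessions:
            skipped_unmapped += 1
            continue
        prop = aspect_property(rec.aspect, vocab)
        term = go_term_iri(rec.go_id)
        for acc in accessions:
            gene = refseq_uri(acc)
            g.add((gene, vocab.rdf_type, vocab.transcript_class))
            g.add((gene, prop, term))
    if skipped_unmapped or skipped_unknown_term:
        logger.info(
            "annotations_to_rdf: skipped %d record(s) with unmapped symbols and %d with terms absent from the scheme",
            skipped_unmapped,
            skipped_unknown_term,
        )
    return g


def _annotation_properties(vocab: Vocabulary) -> Tuple[URIRef, URIRef, URIRef]:
    return (vocab.participates_in, vocab.has_function, vocab.part_of)


ANNOTATION_PROPERTIES = _annotation_properties(make_vocabulary())


def entail_go(graph: Graph, vocab: Vocabulary | None = None) -> Graph:
    """Materialize annotation propagation up the broader hierarchy.

    For each relation p in {participates_in, has_function, part_of}, adds
    (gene, p, ancestor) for every ancestor of every annotated term, to
    fixpoint.  The result is a superset of the input and the operation is
    idempotent.  Propagation never crosses relations.
    """
    vocab = vocab or make_vocabulary()
    parents: Dict[URIRef, Set[URIRef]] = defaultdict(set)
    for child, parent in graph.subject_objects(vocab.broader):
        parents[child].add(parent)

    anc_cache: Dict[URIRef, Set[URIRef]] = {}

    def ancestors_of(node: URIRef) -> Set[URIRef]:
        # Iterative memoized DFS; the hierarchy is a DAG by construction.
        stack = [node]
        while stack:
            n = stack[-1]
            if n in anc_cache:
                stack.pop()
                continue
            pending = [p for p in parents.get(n, ()) if p not in anc_cache]
            if pending:
                stack.extend(pending)
                continue
            acc: Set[URIRef] = set()
            for p in parents.get(n, ()):
                acc.add(p)
                acc.update(anc_cache[p])
            anc_cache[n] = acc
            stack.pop()
        return anc_cache[node]

    out = Graph()
    for triple in graph:
        out.add(triple)
    for prop in _annotation_properties(vocab):
        for gene, term in graph.subject_objects(prop):
            for anc in ancestors_of(term):
                out.add((gene, prop, anc))
    return out


def ancestors(scheme: ConceptScheme, term: str) -> Set[str]:
    """Proper ancestors of *term* via broader edges (the term itself excluded)."""
    if term not in scheme.terms:
        raise ValueError(f"unknown term {term!r}")
    parents: Dict[str, Set[str]] = defaultdict(set)
    for child, parent in scheme.broader_edges:
        parents[child].add(parent)
    seen: Set[str] = set()
    frontier = list(parents.get(term, ()))
    while frontier:
        node = frontier.pop()
        if node in seen:
            continue
        seen.add(node)
        frontier.extend(parents.get(node, ()))
    return seen
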