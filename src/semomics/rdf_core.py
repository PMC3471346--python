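"""Triple-level data model, the fixed vocabulary of IRIs, and graph plumbing.

The interchange unit throughout the package is an :class:`rdflib.Graph` with
set semantics over ``(subject, predicate, object)`` triples.  Subjects and
predicates are :class:`rdflib.URIRef`; objects are IRIs or typed literals.
Blank nodes are never emitted: every entity receives a deterministic IRI so
that graph merging is plain set union and serialized output is reproducible.

The vocabulary collects the small set of borrowed ontology terms used to
describe quantitative observations (IAO/OBI), annotation relations (RO),
taxonomy structure (SKOS) and the ad-hoc transcription-factor relations in
the ``k:`` namespace.  Terms with well-known numeric accessions use them
verbatim; label-only terms are pinned once here to their canonical OBO IRIs
and treated as opaque identifiers everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Union

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD

__all__ = [
    "OBO",
    "RO",
    "SKOS_NS",
    "DC",
    "K",
    "GO_NS",
    "BIO2RDF_REFSEQ",
    "Vocabulary",
    "make_vocabulary",
    "merge_graphs",
    "serialize",
    "parse",
    "graphs_equal",
    "GraphParseError",
]

# Namespace strings (kept as plain strings; URIRefs are built where needed).
OBO = "http://purl.obolibrary.org/obo/"
RO = "http://www.obofoundry.org/ro/ro.owl#"
SKOS_NS = "http://www.w3.org/2004/02/skos/core#"
DC = "http://purl.org/dc/elements/1.1/"
K = "http://krauthammerlab.med.yale.edu/"
GO_NS = "http://purl.org/obo/owl/GO#"
BIO2RDF_REFSEQ = "http://bio2rdf.org/refseq:"

Node = Union[URIRef, Literal]


class GraphParseError(ValueError):
    """Raised when a serialized graph cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class Vocabulary:
    """The fixed set of IRIs used across all semantic models.

    All fields are absolute IRIs and pairwise distinct.  ``is_about``,
    ``has_measurement_value`` and ``cell_culture`` carry the numeric
    accessions used verbatim in the case-study queries.
    """

    is_about: URIRef
    has_measurement_value: URIRef
    cell_culture: URIRef
    part_of: URIRef
    participates_in: URIRef
    has_function: URIRef
    broader: URIRef
    concept: URIRef
    corresponds_to: URIRef
    regulates: URIRef
    coregulates: URIRef
    indirectly_coregulates: URIRef
    dc_title: URIRef
    dc_identifier: URIRef
    measurement_datum_class: URIRef
    data_set_class: URIRef
    transcript_class: URIRef
    is_quality_measurement_of: URIRef
    has_measurement_unit_label: URIRef
    rdf_type: URIRef

    def __post_init__(self) -> None:
        values = [getattr(self, f.name) for f in fields(self)]
        if len(set(values)) != len(values):
            raise ValueError("vocabulary IRIs must be pairwise distinct")


_VOCAB = Vocabulary(
    is_about=URIRef(OBO + "IAO_0000136"),
    has_measurement_value=URIRef(OBO + "IAO_0000004"),
    cell_culture=URIRef(OBO + "OBI_0100060"),
    part_of=URIRef(RO + "part_of"),
    participates_in=URIRef(RO + "participates_in"),
    has_function=URIRef(RO + "has_function"),
    broader=URIRef(SKOS_NS + "broader"),
    concept=URIRef(SKOS_NS + "Concept"),
    corresponds_to=URIRef(K + "corresponds_to"),
    regulates=URIRef(K + "regulates"),
    coregulates=URIRef(K + "coregulates"),
    indirectly_coregulates=URIRef(K + "indirectly_coregulates"),
    dc_title=URIRef(DC + "title"),
    dc_identifier=URIRef(DC + "identifier"),
    measurement_datum_class=URIRef(OBO + "IAO_0000109"),
    data_set_class=URIRef(OBO + "IAO_0000100"),
    transcript_class=URIRef(OBO + "SO_0000673"),
    is_quality_measurement_of=URIRef(OBO + "IAO_0000221"),
    has_measurement_unit_label=URIRef(OBO + "IAO_0000039"),
    rdf_type=RDF.type,
)


def make_vocabulary() -> Vocabulary:
    """Return the constant vocabulary shared by all modules."""
    return _VOCAB


def merge_graphs(graphs: Iterable[Graph]) -> Graph:
    """Set union of the triples of *graphs* into a fresh graph.

    Nodes with identical IRIs unify automatically (that is the point of the
    shared Bio2RDF RefSeq IRIs); the inputs are left unchanged.
    """
    merged = Graph()
    for g in graphs:
        for triple in g:
            merged.add(triple)
    return merged


class _ExactTurtleSerializer:
    """Turtle serializer that keeps xsd:double lexical forms intact.

    The stock Turtle writer renders doubles through ``%e`` at six
    significant digits, so measurement values would not survive a
    serialization round trip; writing them in quoted typed form preserves
    the lexical form (and therefore numeric comparisons) exactly.
    """

    def __new__(cls, store):
        from rdflib.plugins.serializers.turtle import TurtleSerializer

        class Impl(TurtleSerializer):
            def label(self, node, position):
                if isinstance(node, Literal) and node.datatype == XSD.double:
                    return node._literal_n3(
                        use_plain=False,
                        qname_callback=lambda dt: self.get_pname(dt, False),
                    )
                return super().label(node, position)

        return Impl(store)


def _register_exact_turtle() -> None:
    from rdflib import plugin
    from rdflib.serializer import Serializer

    plugin.register("turtle-exact", Serializer, __name__, "_ExactTurtleSerializer")


_register_exact_turtle()

# Parsing accepts standard Turtle; writing goes through the exact variant.
_FORMATS = {"turtle": "turtle", "ntriples": "nt"}
_WRITE_FORMATS = {"turtle": "turtle-exact", "ntriples": "nt"}


def serialize(graph: Graph, format: str = "turtle") -> bytes:
    """Serialize *graph* to UTF-8 bytes in ``turtle`` or ``ntriples``."""
    if format not in _WRITE_FORMATS:
        raise ValueError(f"unsupported format {format!r}; expected one of {sorted(_WRITE_FORMATS)}")
    return graph.serialize(format=_WRITE_FORMATS[format], encoding="utf-8")


def parse(data: Union[bytes, str], format: str = "turtle") -> Graph:
    """Parse a serialized document back into a graph.

    Raises :class:`GraphParseError` naming the offending line on malformed
    input.  ``parse(serialize(g, f), f)`` is the identity on triple sets.
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; expected one of {sorted(_FORMATS)}")
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    g = Graph()
    try:
        g.parse(data=data, format=_FORMATS[format])
    except Exception as exc:  # rdflib raises several parser exception types
        raise GraphParseError(_describe_parse_failure(data, format, exc)) from exc
    return g


def _describe_parse_failure(data: str, format: str, exc: Exception) -> str:
    message = str(exc)
    if "line" in message.lower():
        return message
    # Not every parser failure carries a position; locate the first prefix of
    # the document that fails while the one before it still parses.
    lines = data.splitlines()
    last_good = 0
    for lineno in range(1, len(lines) + 1):
        probe = Graph()
        try:
            probe.parse(data="\n".join(lines[:lineno]) + "\n", format=_FORMATS[format])
            last_good = lineno
        except Exception:
            if lineno == last_good + 1:
                return f"line {lineno}: {message}"
    return message


def graphs_equal(a: Graph, b: Graph) -> bool:
    """Triple-set equality (sufficient here because blank nodes are not used)."""
    return set(a) == set(b)
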