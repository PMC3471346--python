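"""Ingest quantitative observation tables and map them to RDF.

One *observation* is a single quantitative data point — a relative promoter
methylation value, an expression post/pre-treatment ratio — carrying
provenance pointers to the dataset it belongs to, the sample (cell culture)
it was measured on and the reporter (a RefSeq transcript) it is about.

The RDF mapping casts observations as IAO *measurement datum* instances,
samples as OBI *cell culture* instances and reporters as SO *transcript*
instances, with values attached through IAO *has measurement value* and
names through Dublin Core *title*/*identifier*.  Reporters get Bio2RDF-style
RefSeq IRIs, the merge key shared with the annotation and network models.
"""

from __future__ import annotations

import hashlib
import io
import logging
import re
from dataclasses import dataclass
from math import isfinite
from typing import Iterable, List, Union
from urllib.parse import quote

import pandas as pd
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import XSD

from .rdf_core import BIO2RDF_REFSEQ, K, Vocabulary, make_vocabulary

__all__ = [
    "ObservationRecord",
    "SchemaError",
    "RowParseError",
    "read_observation_table",
    "refseq_uri",
    "observation_iri",
    "dataset_iri",
    "sample_iri",
    "map_to_rdf",
    "describe_sample",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("dataset", "sample", "reporter_id", "value")
OPTIONAL_COLUMNS = ("reporter_title", "measure", "unit")


class SchemaError(ValueError):
    """An observation table is missing required columns."""


class RowParseError(ValueError):
    """A data row cannot be interpreted; the message names the line."""


@dataclass(frozen=True)
class ObservationRecord:
    """One quantitative data point with its provenance."""

    dataset_title: str
    sample_title: str
    reporter_id: str
    value: float
    reporter_title: str = ""
    measure_quality: str = ""
    unit_label: str = ""

    def __post_init__(self) -> None:
        if not self.dataset_title or not self.sample_title or not self.reporter_id:
            raise ValueError("dataset_title, sample_title and reporter_id must be non-empty")
        if not isfinite(self.value):
            raise ValueError("observation value must be finite")


def read_observation_table(source: Union[str, io.TextIOBase]) -> List[ObservationRecord]:
    """Read a tab-separated observation table.

    The header must name the columns ``dataset``, ``sample``, ``reporter_id``
    and ``value``; ``reporter_title``, ``measure`` and ``unit`` are optional.
    Row order is preserved.  A missing column raises :class:`SchemaError`;
    an unparseable value raises :class:`RowParseError` naming the line
    (line 1 is the header).
    """
    if isinstance(source, str):
        frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"observation table is missing required column(s): {', '.join(missing)}")
    has_title = "reporter_title" in frame.columns
    has_measure = "measure" in frame.columns
    has_unit = "unit" in frame.columns
    records: List[ObservationRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        raw = getattr(row, "value")
        try:
            value = float(raw)
        except ValueError:
            raise RowParseError(f"line {lineno}: cannot parse value {raw!r} as a number") from None
        try:
            records.append(
                ObservationRecord(
                    dataset_title=getattr(row, "dataset"),
                    sample_title=getattr(row, "sample"),
                    reporter_id=getattr(row, "reporter_id"),
                    value=value,
                    reporter_title=getattr(row, "reporter_title") if has_title else "",
                    measure_quality=getattr(row, "measure") if has_measure else "",
                    unit_label=getattr(row, "unit") if has_unit else "",
                )
            )
        except ValueError as exc:
            raise RowParseError(f"line {lineno}: {exc}") from None
    return records


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def refseq_uri(accession: str) -> URIRef:
    """Deterministic Bio2RDF-style IRI for a RefSeq accession.

    Version suffixes (``NM_000546.3`` -> ``NM_000546``) are stripped so that
    the same transcript joins across sources regardless of release.
    """
    accession = accession.strip()
    if not accession:
        raise ValueError("empty RefSeq accession")
    return URIRef(BIO2RDF_REFSEQ + _VERSION_SUFFIX.sub("", accession))


def observation_iri(dataset_title: str, sample_title: str, reporter_id: str, measure: str = "") -> URIRef:
    """Content-addressed IRI for an observation node (stable across runs)."""
    key = "\x1f".join((dataset_title, sample_title, reporter_id, measure))
    digest = hashlib.sha1(key.encode("utf-8")).hexdigest()[:16]
    return URIRef(K + "observation/" + digest)


def dataset_iri(title: str) -> URIRef:
    return URIRef(K + "dataset/" + quote(title, safe=""))


def sample_iri(title: str) -> URIRef:
    return URIRef(K + "sample/" + quote(title, safe=""))


def map_to_rdf(records: Iterable[ObservationRecord], vocab: Vocabulary | None = None) -> Graph:
    """Map observation records to the semantic model.

    Per record the graph receives the observation node (typed measurement
    datum) with its value, dataset membership (``ro:part_of``) and *is about*
    links to its sample and reporter; dataset and sample nodes are shared
    across records with the same title.  Duplicate
    ``(dataset, sample, reporter)`` keys keep the last row (logged).
    """
    vocab = vocab or make_vocabulary()
    deduped: dict[tuple[str, str, str], ObservationRecord] = {}
    dropped = 0
    for rec in records:
        key = (rec.dataset_title, rec.sample_title, rec.reporter_id)
        if key in deduped:
            dropped += 1
        deduped[key] = rec
    if dropped:
        logger.warning("map_to_rdf: %d duplicate (dataset, sample, reporter) row(s); last row wins", dropped)

    g = Graph()
    seen_datasets: set[str] = set()
    seen_samples: set[str] = set()
    seen_reporters: set[str] = set()
    for rec in deduped.values():
        obs = observation_iri(rec.dataset_title, rec.sample_title, rec.reporter_id, rec.measure_quality)
        ds = dataset_iri(rec.dataset_title)
        samp = sample_iri(rec.sample_title)
        rep = refseq_uri(rec.reporter_id)
        g.add((obs, vocab.rdf_type, vocab.measurement_datum_class))
        g.add((obs, vocab.has_measurement_value, Literal(rec.value, datatype=XSD.double)))
        g.add((obs, vocab.part_of, ds))
        g.add((obs, vocab.is_about, samp))
        g.add((obs, vocab.is_about, rep))
        if rec.measure_quality:
            g.add((obs, vocab.is_quality_measurement_of, Literal(rec.measure_quality)))
        if rec.unit_label:
            g.add((obs, vocab.has_measurement_unit_label, Literal(rec.unit_label)))
        if rec.dataset_title not in seen_datasets:
            seen_datasets.add(rec.dataset_title)
            g.add((ds, vocab.rdf_type, vocab.data_set_class))
            g.add((ds, vocab.dc_title, Literal(rec.dataset_title)))
        if rec.sample_title not in seen_samples:
            seen_samples.add(rec.sample_title)
            g.add((samp, vocab.rdf_type, vocab.cell_culture))
            g.add((samp, vocab.dc_title, Literal(rec.sample_title)))
        if rec.reporter_id not in seen_reporters:
            seen_reporters.add(rec.reporter_id)
            g.add((rep, vocab.rdf_type, vocab.transcript_class))
            g.add((rep, vocab.dc_identifier, Literal(rec.reporter_id)))
            if rec.reporter_title:
                g.add((rep, vocab.dc_title, Literal(rec.reporter_title)))
    return g


def describe_sample(graph: Graph, sample_title: str, vocab: Vocabulary | None = None) -> Graph:
    """Per-sample subgraph extraction (DESCRIBE-style).

    Returns every triple whose subject is the sample with the given title,
    one of its observations, or one of those observations' datasets or
    reporters.  An absent sample title yields an empty graph.
    """
    vocab = vocab or make_vocabulary()
    title = Literal(sample_title)
    samples = {
        s
        for s in graph.subjects(vocab.rdf_type, vocab.cell_culture)
        if (s, vocab.dc_title, title) in graph
    }
    nodes = set(samples)
    for samp in samples:
        for obs in graph.subjects(vocab.is_about, samp):
            datasets = set(graph.objects(obs, vocab.part_of))
            reporters = set(graph.objects(obs, vocab.is_about)) - samples
            if not datasets or not reporters:
                continue  # the extraction pattern requires both links
            nodes.add(obs)
            nodes.update(datasets)
            nodes.update(reporters)
    out = Graph()
    for triple in graph:
        if triple[0] in nodes:
            out.add(triple)
    return out
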