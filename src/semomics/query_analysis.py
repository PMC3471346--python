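"""SPARQL querying and the Decitabine-style sensitivity analyses.

The analyses interrogate a merged, entailed graph holding two quantitative
datasets per cell line — relative promoter methylation before demethylating
treatment and post/pre expression ratios after — together with propagated
GO annotations and the TF coregulation closure:

* :func:`pathway_contrast_counts` — per sample, how many genes passing both
  filters (methylation > 2, ratio > 1 by default) participate in apoptosis,
  against the analogous cell-proliferation count;
* :func:`tf_candidates` — genes passing the methylation filter and a relaxed
  expression filter (> 0.5) that express a transcription factor;
* :func:`tf_regulated_high_counts` — per sample, how many highly expressed
  genes fall in a TF's sphere of influence, with a one-sided Fisher exact
  enrichment p-value over the genes observed in the ratio dataset;
* :func:`tf_pathway_ratio` — the apoptosis vs proliferation split of those
  highly expressed influence-set genes.

Every threshold is a strict ``>`` comparison, matching the FILTER operators
of the stored queries.  All set-logic implementations here are independent
of the SPARQL engine route (:func:`run_sparql`), and the two are checked
against each other in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import comb, isfinite
from typing import Dict, List, Sequence, Set, Tuple, Union

from rdflib import Graph, Literal, URIRef

from .rdf_core import Vocabulary, make_vocabulary
from .tf_semantics import tf_iri

__all__ = [
    "ThresholdConfig",
    "PathwayCountRow",
    "TfCandidateRow",
    "ContingencyTable",
    "TfEnrichmentRow",
    "TfPathwayRatioRow",
    "MissingDatasetError",
    "QueryError",
    "run_sparql",
    "pathway_contrast_counts",
    "tf_candidates",
    "fisher_exact",
    "tf_regulated_high_counts",
    "tf_pathway_ratio",
]


class MissingDatasetError(ValueError):
    """A dataset title required by an analysis is absent from the graph."""


class QueryError(ValueError):
    """A SPARQL query failed to parse; the message reports the position."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Analysis cutoffs and dataset titles (all comparisons are strict >)."""

    methylation_min: float = 2.0
    expression_ratio_min: float = 1.0
    tf_expression_ratio_min: float = 0.5
    high_expression_min: float = 1.0
    methylation_dataset_title: str = "Methylation Relative"
    ratio_dataset_title: str = "AZA Pre-Post Treatment Ratios"

    def __post_init__(self) -> None:
        for name in ("methylation_min", "expression_ratio_min", "tf_expression_ratio_min", "high_expression_min"):
            if not isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class PathwayCountRow:
    sample_title: str
    count_a: int
    count_b: int
    ratio: float


@dataclass(frozen=True)
class TfCandidateRow:
    reporter: URIRef
    tf: URIRef
    sample_title: str
    methylation_value: float
    ratio_value: float


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2x2 counts: a = regulated & high, b = regulated & not high,
    c = not regulated & high, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TfEnrichmentRow:
    sample_title: str
    tf: URIRef
    high_regulated_count: int
    total_high_count: int
    p_value: float


@dataclass(frozen=True)
class TfPathwayRatioRow:
    sample_title: str
    count_a: int
    count_b: int
    ratio: float


class _GraphStats:
    """Cardinality statistics used to order BGP patterns by selectivity."""

    def __init__(self, graph: Graph):
        self.graph = graph
        per_pred: Dict = {}
        n = 0
        for s, p, o in graph:
            n += 1
            entry = per_pred.setdefault(p, [0, set(), set()])
            entry[0] += 1
            entry[1].add(s)
            entry[2].add(o)
        self.total = n
        self.per_pred = {
            p: (c, max(1, len(subs)), max(1, len(objs))) for p, (c, subs, objs) in per_pred.items()
        }
        self._pattern_counts: Dict = {}

    def _base_count(self, s, p, o) -> float:
        """Matches for the pattern with variables treated as wildcards."""
        from rdflib.term import Variable

        s_c = None if isinstance(s, Variable) else s
        p_c = None if isinstance(p, Variable) else p
        o_c = None if isinstance(o, Variable) else o
        if s_c is None and o_c is None:
            if p_c is None:
                return float(self.total)
            return float(self.per_pred.get(p_c, (0, 1, 1))[0])
        key = (s_c, p_c, o_c)
        if key not in self._pattern_counts:
            self._pattern_counts[key] = sum(1 for _ in self.graph.triples(key))
        return float(self._pattern_counts[key])

    def fanout(self, triple, bound) -> float:
        """Estimated solutions produced per existing solution row."""
        from rdflib.term import Variable

        s, p, o = triple
        est = self._base_count(s, p, o)
        count, d_subj, d_obj = self.per_pred.get(
            p if not isinstance(p, Variable) else None, (self.total, 1, 1)
        )
        s_known = not isinstance(s, Variable) or s in bound
        o_known = not isinstance(o, Variable) or o in bound
        if isinstance(s, Variable) and s in bound:
            est /= d_subj
        if isinstance(o, Variable) and o in bound:
            est /= d_obj
        if s_known and o_known:
            est = min(est, 0.5)  # a pure prune, always cheap
        return est


def _reorder_bgps(node, stats: "_GraphStats") -> None:
    """Greedy selectivity-based reordering of BGP triple patterns, in place.

    Basic graph patterns are conjunctions, so execution order is free.  The
    engine evaluates them in sequence with nested-loop joins, so each next
    pattern is chosen to minimize estimated fan-out given the variables
    already bound — without this, queries whose two halves join on a late
    shared variable blow up combinatorially.
    """
    from rdflib.term import Variable

    if getattr(node, "name", None) == "BGP":
        triples = list(node["triples"])
        ordered = []
        bound: set = set()
        while triples:
            best = min(triples, key=lambda t: stats.fanout(t, bound))
            triples.remove(best)
            ordered.append(best)
            bound.update(term for term in best if isinstance(term, Variable))
        node["triples"] = ordered
    values = node.values() if hasattr(node, "values") else []
    for value in list(values):
        if hasattr(value, "name"):
            _reorder_bgps(value, stats)
        elif isinstance(value, list):
            for item in value:
                if hasattr(item, "name"):
                    _reorder_bgps(item, stats)


def run_sparql(graph: Graph, query_text: str):
    """Run a SELECT or DESCRIBE query; returns rdflib result rows (or a
    graph for DESCRIBE).  Parse failures raise :class:`QueryError` with the
    parser's position information."""
    from rdflib.plugins.sparql import prepareQuery

    try:
        prepared = prepareQuery(query_text)
        _reorder_bgps(prepared.algebra, _GraphStats(graph))
        result = graph.query(prepared)
    except Exception as exc:
        message = str(exc)
        if "Expected" in message or "line" in message.lower() or "char" in message.lower():
            raise QueryError(f"SPARQL parse error: {message}") from exc
        raise
    if result.type == "DESCRIBE" or result.type == "CONSTRUCT":
        return result.graph
    return list(result)


# ---------------------------------------------------------------------------
# Graph extraction helpers (set-logic route, independent of the SPARQL engine)
# ---------------------------------------------------------------------------


def _dataset_values(graph: Graph, dataset_title: str, vocab: Vocabulary) -> Dict[str, Dict[URIRef, float]]:
    """Per-sample-title reporter -> value map for one dataset title.

    Reporters are the is_about objects that are not typed as cell cultures.
    Raises :class:`MissingDatasetError` when no dataset carries the title.
    """
    title = Literal(dataset_title)
    datasets = {ds for ds in graph.subjects(vocab.dc_title, title) if (ds, vocab.rdf_type, vocab.data_set_class) in graph}
    if not datasets:
        raise MissingDatasetError(f"no dataset titled {dataset_title!r} in graph")
    samples = set(graph.subjects(vocab.rdf_type, vocab.cell_culture))
    sample_titles = {s: str(next(graph.objects(s, vocab.dc_title), "")) for s in samples}
    values: Dict[str, Dict[URIRef, float]] = {}
    for ds in datasets:
        for obs in graph.subjects(vocab.part_of, ds):
            val = next(graph.objects(obs, vocab.has_measurement_value), None)
            if val is None:
                continue
            about = set(graph.objects(obs, vocab.is_about))
            obs_samples = about & samples
            reporters = about - samples
            for s in obs_samples:
                for rep in reporters:
                    values.setdefault(sample_titles[s], {})[rep] = float(val)
    return values


def _annotated_genes(graph: Graph, term: URIRef, vocab: Vocabulary) -> Set[URIRef]:
    return set(graph.subjects(vocab.participates_in, term))


def _resolve_term(term: Union[str, URIRef]) -> URIRef:
    if isinstance(term, URIRef):
        return term
    from .go_semantics import go_term_iri

    return go_term_iri(term) if term.startswith("GO:") else URIRef(term)


def pathway_contrast_counts(
    graph: Graph,
    term_a: Union[str, URIRef],
    term_b: Union[str, URIRef],
    thr: ThresholdConfig | None = None,
    mode: str = "report",
    vocab: Vocabulary | None = None,
) -> List[PathwayCountRow]:
    """Per-sample contrast of filtered gene counts for two process terms.

    ``count_a`` is the number of genes participating (after entailment) in
    *term_a* whose methylation exceeds ``methylation_min`` and whose
    expression ratio exceeds ``expression_ratio_min`` in that sample;
    ``count_b`` is the analogue for *term_b*; ``ratio`` is their quotient
    (0 when ``count_b`` is 0).

    In ``report`` mode every sample appears.  In ``strict`` mode only
    samples with both counts >= 1 appear, reproducing the inner-join
    semantics of the stored SPARQL query.  Rows are ordered by sample title.
    """
    vocab = vocab or make_vocabulary()
    thr = thr or ThresholdConfig()
    if mode not in ("report", "strict"):
        raise ValueError(f"mode must be 'report' or 'strict', got {mode!r}")
    meth = _dataset_values(graph, thr.methylation_dataset_title, vocab)
    ratio = _dataset_values(graph, thr.ratio_dataset_title, vocab)
    genes_a = _annotated_genes(graph, _resolve_term(term_a), vocab)
    genes_b = _annotated_genes(graph, _resolve_term(term_b), vocab)
    rows: List[PathwayCountRow] = []
    for sample in sorted(set(meth) | set(ratio)):
        m = meth.get(sample, {})
        r = ratio.get(sample, {})
        passing = {
            g
            for g in set(m) & set(r)
            if m[g] > thr.methylation_min and r[g] > thr.expression_ratio_min
        }
        count_a = len(passing & genes_a)
        count_b = len(passing & genes_b)
        if mode == "strict" and (count_a == 0 or count_b == 0):
            continue
        rows.append(
            PathwayCountRow(
                sample_title=sample,
                count_a=count_a,
                count_b=count_b,
                ratio=count_a / count_b if count_b else 0.0,
            )
        )
    return rows


def tf_candidates(
    graph: Graph,
    thr: ThresholdConfig | None = None,
    vocab: Vocabulary | None = None,
) -> List[TfCandidateRow]:
    """Distinct (gene, TF, sample) rows where the gene expresses the TF and
    passes the methylation and relaxed expression filters in that sample."""
    vocab = vocab or make_vocabulary()
    thr = thr or ThresholdConfig()
    meth = _dataset_values(graph, thr.methylation_dataset_title, vocab)
    ratio = _dataset_values(graph, thr.ratio_dataset_title, vocab)
    observed_reporters = {rep for per in meth.values() for rep in per}
    # corresponds_to is materialized in both directions; orient each pair so
    # the gene side is an observed reporter.
    pairs: Set[Tuple[URIRef, URIRef]] = set()
    for s, o in graph.subject_objects(vocab.corresponds_to):
        if s in observed_reporters:
            pairs.add((s, o))
    rows: List[TfCandidateRow] = []
    for sample in sorted(set(meth) & set(ratio)):
        m, r = meth[sample], ratio[sample]
        for gene, tf in sorted(pairs):
            if gene in m and gene in r and m[gene] > thr.methylation_min and r[gene] > thr.tf_expression_ratio_min:
                rows.append(
                    TfCandidateRow(
                        reporter=gene,
                        tf=tf,
                        sample_title=sample,
                        methylation_value=m[gene],
                        ratio_value=r[gene],
                    )
                )
    return rows


# ---------------------------------------------------------------------------
# Fisher exact test (exact integer hypergeometric arithmetic)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200_000)
def _margin_weights(n: int, r1: int, c1: int) -> Tuple[int, int, Tuple[int, ...]]:
    """Hypergeometric point-mass numerators over the support of a, plus the
    support minimum and the common denominator C(n, c1)."""
    a_min = max(0, r1 + c1 - n)
    a_max = min(r1, c1)
    weights = tuple(comb(r1, x) * comb(n - r1, c1 - x) for x in range(a_min, a_max + 1))
    return a_min, comb(n, c1), weights


def fisher_exact(table: Union[ContingencyTable, Tuple[int, int, int, int]], sided: str = "greater") -> float:
    """Exact hypergeometric p-value for a 2x2 table with fixed margins.

    ``greater`` is the upper tail P(X >= a); ``two_sided`` sums every table
    (with the same margins) whose point probability does not exceed that of
    the observed table.  Computed with exact integer arithmetic, so the
    result is the correctly rounded float of the exact rational p-value.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    if sided not in ("greater", "two_sided"):
        raise ValueError(f"sided must be 'greater' or 'two_sided', got {sided!r}")
    n = table.n
    if n == 0:
        raise ValueError("empty contingency table")
    r1 = table.a + table.b
    c1 = table.a + table.c
    a_min, total, weights = _margin_weights(n, r1, c1)
    idx = table.a - a_min
    if sided == "greater":
        numerator = sum(weights[idx:])
    else:
        observed = weights[idx]
        numerator = sum(w for w in weights if w <= observed)
    return float(Fraction(numerator, total))


# ---------------------------------------------------------------------------
# TF enrichment analyses
# ---------------------------------------------------------------------------


def _influence_set(graph: Graph, tf: URIRef, vocab: Vocabulary, include_influence: bool) -> Set[URIRef]:
    direct = set(graph.objects(tf, vocab.regulates))
    expressing = set(graph.objects(tf, vocab.corresponds_to))
    if not direct and not expressing:
        raise ValueError(f"transcription factor {tf} is absent from the graph")
    influence = set(direct)
    if include_influence:
        for gene in expressing:
            influence.update(graph.objects(gene, vocab.coregulates))
            influence.update(graph.objects(gene, vocab.indirectly_coregulates))
    return influence


def _resolve_tf(tf: Union[str, URIRef]) -> URIRef:
    if isinstance(tf, URIRef):
        return tf
    return tf_iri(tf) if "://" not in tf else URIRef(tf)


def tf_regulated_high_counts(
    graph: Graph,
    tf: Union[str, URIRef],
    thr: ThresholdConfig | None = None,
    universe: str = "observed_genes",
    include_influence: bool = True,
    vocab: Vocabulary | None = None,
) -> List[TfEnrichmentRow]:
    """Per-sample counts of highly expressed genes within a TF's sphere of
    influence, with a one-sided (greater) Fisher exact enrichment p-value.

    The universe is the set of genes observed in the ratio dataset for the
    sample; "high" means ratio > ``high_expression_min``; "regulated" means
    direct targets united with the coregulation influence sets (restrict to
    direct targets with ``include_influence=False``).
    """
    vocab = vocab or make_vocabulary()
    thr = thr or ThresholdConfig()
    if universe != "observed_genes":
        raise ValueError(f"unsupported universe {universe!r}")
    tf_node = _resolve_tf(tf)
    influence = _influence_set(graph, tf_node, vocab, include_influence)
    ratio = _dataset_values(graph, thr.ratio_dataset_title, vocab)
    rows: List[TfEnrichmentRow] = []
    for sample in sorted(ratio):
        per = ratio[sample]
        observed = set(per)
        high = {g for g in observed if per[g] > thr.high_expression_min}
        regulated = influence & observed
        a = len(high & regulated)
        b = len(regulated) - a
        c = len(high) - a
        d = len(observed) - len(regulated) - c
        p = fisher_exact(ContingencyTable(a, b, c, d), "greater") if observed else 1.0
        rows.append(
            TfEnrichmentRow(
                sample_title=sample,
                tf=tf_node,
                high_regulated_count=a,
                total_high_count=len(high),
                p_value=p,
            )
        )
    return rows


def tf_pathway_ratio(
    graph: Graph,
    tf: Union[str, URIRef],
    term_a: Union[str, URIRef],
    term_b: Union[str, URIRef],
    thr: ThresholdConfig | None = None,
    include_influence: bool = True,
    vocab: Vocabulary | None = None,
) -> List[TfPathwayRatioRow]:
    """Among each sample's highly expressed genes in the TF's influence set,
    the count annotated (after entailment) to *term_a* and its ratio to the
    *term_b* count (0 when the latter is 0)."""
    vocab = vocab or make_vocabulary()
    thr = thr or ThresholdConfig()
    tf_node = _resolve_tf(tf)
    influence = _influence_set(graph, tf_node, vocab, include_influence)
    genes_a = _annotated_genes(graph, _resolve_term(term_a), vocab)
    genes_b = _annotated_genes(graph, _resolve_term(term_b), vocab)
    ratio = _dataset_values(graph, thr.ratio_dataset_title, vocab)
    rows: List[TfPathwayRatioRow] = []
    for sample in sorted(ratio):
        per = ratio[sample]
        high_influence = {g for g in influence if g in per and per[g] > thr.high_expression_min}
        count_a = len(high_influence & genes_a)
        count_b = len(high_influence & genes_b)
        rows.append(
            TfPathwayRatioRow(
                sample_title=sample,
                count_a=count_a,
                count_b=count_b,
                ratio=count_a / count_b if count_b else 0.0,
            )
        )
    return rows
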