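"""SPARQL engine vs set-logic agreement, Fisher exactness, analyses."""

import numpy as np
import pytest
import scipy.stats
from rdflib import Graph, Literal, URIRef

from oracles import fisher_enumeration
from semomics.observation_store import ObservationRecord, map_to_rdf, refseq_uri
from semomics.go_semantics import go_term_iri
from semomics.queries import PATHWAY_CONTRAST_QUERY, TF_CANDIDATE_QUERY
from semomics.query_analysis import (
    ContingencyTable,
    MissingDatasetError,
    QueryError,
    ThresholdConfig,
    fisher_exact,
    pathway_contrast_counts,
    run_sparql,
    tf_candidates,
    tf_pathway_ratio,
    tf_regulated_high_counts,
)
from semomics.rdf_core import merge_graphs
from semomics.synthetic_data import APOPTOSIS_TERM, PROLIFERATION_TERM
from semomics.tf_semantics import TfRecord, entail_tf, tf_iri, tf_to_rdf

METH = "Methylation Relative"
RATIO = "AZA Pre-Post Treatment Ratios"


def _obs(sample, dataset, gene, value):
    return ObservationRecord(dataset_title=dataset, sample_title=sample, reporter_id=gene, value=value)


def _planted_graph(vocab):
    """Hand-planted fixture: S1 has 3 apoptosis and 2 proliferation genes
    passing both filters; S2 has 1 and 0."""
    records = []
    apop = [f"NM_{i:06d}" for i in range(1, 5)]  # NM_1..4 apoptosis-annotated
    prolif = [f"NM_{i:06d}" for i in range(5, 8)]  # NM_5..7 proliferation
    passing_s1 = apop[:3] + prolif[:2]
    for gene in apop + prolif:
        for sample in ("S1", "S2"):
            hit = (sample == "S1" and gene in passing_s1) or (sample == "S2" and gene == apop[0])
            records.append(_obs(sample, METH, gene, 5.0 if hit else 0.5))
            records.append(_obs(sample, RATIO, gene, 2.0 if hit else 0.5))
    g = map_to_rdf(records)
    for gene in apop:
        g.add((refseq_uri(gene), vocab.participates_in, go_term_iri(APOPTOSIS_TERM)))
    for gene in prolif:
        g.add((refseq_uri(gene), vocab.participates_in, go_term_iri(PROLIFERATION_TERM)))
    return g


class TestRunSparql:
    def test_select_over_empty_graph(self):
        assert run_sparql(Graph(), "SELECT ?s WHERE { ?s ?p ?o }") == []

    def test_count_distinct_deduplicates(self, vocab):
        g = Graph()
        s = URIRef("http://example.org/s")
        g.add((s, vocab.dc_title, Literal("x")))
        g.add((s, vocab.dc_identifier, Literal("y")))
        rows = run_sparql(
            g, "SELECT (count(distinct ?s) as ?n) WHERE { ?s ?p ?o }"
        )
        assert int(rows[0]["n"]) == 1

    def test_parse_error_reported_with_position(self):
        with pytest.raises(QueryError):
            run_sparql(Graph(), "SELECT ?s WHERE { ?s ?p }")


class TestPathwayContrastCounts:
    def test_empty_observations_is_an_error_without_datasets(self):
        with pytest.raises(MissingDatasetError, match="Methylation Relative"):
            pathway_contrast_counts(Graph(), APOPTOSIS_TERM, PROLIFERATION_TERM)

    def test_planted_counts_and_ratio(self, vocab):
        g = _planted_graph(vocab)
        rows = pathway_contrast_counts(g, APOPTOSIS_TERM, PROLIFERATION_TERM)
        by_sample = {r.sample_title: r for r in rows}
        assert (by_sample["S1"].count_a, by_sample["S1"].count_b) == (3, 2)
        assert by_sample["S1"].ratio == pytest.approx(1.5)
        # S2 has a zero proliferation count: ratio reported as 0
        assert (by_sample["S2"].count_a, by_sample["S2"].count_b, by_sample["S2"].ratio) == (1, 0, 0.0)

    def test_strict_mode_drops_zero_denominator_samples(self, vocab):
        rows = pathway_contrast_counts(
            _planted_graph(vocab), APOPTOSIS_TERM, PROLIFERATION_TERM, mode="strict"
        )
        assert [r.sample_title for r in rows] == ["S1"]

    def test_child_term_counts_after_entailment(self, vocab, small_bundle, small_graph):
        """A gene annotated only to a descendant of the apoptosis root is
        still counted for the root after propagation."""
        truth = small_bundle.truth
        direct_to_root = {
            acc
            for acc, terms in truth.annotations.annotations.items()
            if APOPTOSIS_TERM in terms
        }
        apoptosis_class = {
            acc for acc, cls in truth.annotations.gene_class.items() if cls == "apoptosis"
        }
        assert direct_to_root < apoptosis_class  # some genes only via children
        rows = pathway_contrast_counts(small_graph, APOPTOSIS_TERM, PROLIFERATION_TERM)
        for row in rows:
            expected = len(truth.observations.hits_by_class[row.sample_title]["apoptosis"])
            assert row.count_a == expected


class TestTfCandidates:
    def test_no_corresponds_to_gives_empty(self, vocab):
        g = _planted_graph(vocab)
        assert tf_candidates(g) == []

    def test_planted_single_candidate(self, vocab):
        g = _planted_graph(vocab)
        tf_graph = tf_to_rdf([TfRecord(tf_id="TF_X", expressing_genes={"NM_000001"})])
        merged = merge_graphs([g, tf_graph])
        rows = tf_candidates(merged)
        passing = [(r.sample_title, str(r.tf)) for r in rows]
        assert passing == [
            ("S1", str(tf_iri("TF_X"))),
            ("S2", str(tf_iri("TF_X"))),
        ]

    def test_threshold_is_strict(self, vocab):
        records = [_obs("S1", METH, "NM_000001", 5.0), _obs("S1", RATIO, "NM_000001", 0.5)]
        g = map_to_rdf(records)
        tf_graph = tf_to_rdf([TfRecord(tf_id="TF_X", expressing_genes={"NM_000001"})])
        merged = merge_graphs([g, tf_graph])
        assert tf_candidates(merged) == []  # ratio == cutoff 0.5 exactly


class TestFisherExact:
    def test_degenerate_margin_gives_one(self):
        assert fisher_exact(ContingencyTable(0, 0, 0, 10), "greater") == 1.0
        assert fisher_exact(ContingencyTable(0, 0, 0, 10), "two_sided") == 1.0

    def test_extreme_table_closed_form(self):
        # P = 1 / C(10,5) = 1/252
        assert fisher_exact(ContingencyTable(5, 0, 0, 5), "greater") == pytest.approx(1 / 252, abs=1e-15)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable(0, 0, 0, 0), "greater")

    @pytest.mark.parametrize("sided", ["greater", "two_sided"])
    def test_random_tables_match_enumeration_oracle(self, sided):
        rng = np.random.default_rng(17)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact(ContingencyTable(a, b, c, d), sided)
            assert ours == pytest.approx(fisher_enumeration(a, b, c, d, sided), abs=1e-12)
            assert 0.0 <= ours <= 1.0

    def test_against_scipy_cross_check(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            ours_g = fisher_exact(ContingencyTable(a, b, c, d), "greater")
            ours_2 = fisher_exact(ContingencyTable(a, b, c, d), "two_sided")
            _, p_g = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            _, p_2 = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert ours_g == pytest.approx(p_g, rel=1e-9, abs=1e-12)
            assert ours_2 == pytest.approx(p_2, rel=1e-7, abs=1e-12)

    def test_point_masses_sum_to_one_over_margin(self):
        # All tables with margins r1=7, c1=5, n=12
        total = sum(
            np.exp(scipy.stats.hypergeom.logpmf(a, 12, 7, 5)) for a in range(0, 6)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


def _tf_enrichment_fixture(vocab):
    """20 observed genes in S1; TF regulates G1..G10 of which 4 are high;
    6 high genes total."""
    records = []
    high = {f"NM_{i:06d}" for i in (1, 2, 3, 4, 11, 12)}
    for i in range(1, 21):
        gene = f"NM_{i:06d}"
        records.append(_obs("S1", RATIO, gene, 3.0 if gene in high else 0.5))
        records.append(_obs("S1", METH, gene, 0.5))
    g = map_to_rdf(records)
    regulated = {f"NM_{i:06d}" for i in range(1, 11)}
    tf_graph = entail_tf(tf_to_rdf([TfRecord(tf_id="TF_X", regulated_genes=regulated)]))
    return merge_graphs([g, tf_graph])


class TestTfRegulatedHighCounts:
    def test_planted_fixture_matches_enumeration(self, vocab):
        merged = _tf_enrichment_fixture(vocab)
        (row,) = tf_regulated_high_counts(merged, "TF_X")
        assert (row.high_regulated_count, row.total_high_count) == (4, 6)
        # a=4 high&regulated, b=6 regulated&low, c=2 high&unregulated, d=8
        assert row.p_value == pytest.approx(fisher_enumeration(4, 6, 2, 8, "greater"), abs=1e-12)

    def test_tf_without_observed_targets(self, vocab):
        records = [_obs("S1", RATIO, "NM_000001", 2.0), _obs("S1", METH, "NM_000001", 1.0)]
        g = map_to_rdf(records)
        tf_graph = tf_to_rdf([TfRecord(tf_id="TF_Y", regulated_genes={"NM_099999"})])
        (row,) = tf_regulated_high_counts(merge_graphs([g, tf_graph]), "TF_Y")
        assert row.high_regulated_count == 0 and row.p_value == 1.0

    def test_absent_tf_rejected(self, vocab):
        records = [_obs("S1", RATIO, "NM_000001", 2.0)]
        with pytest.raises(ValueError, match="absent"):
            tf_regulated_high_counts(map_to_rdf(records), "NOPE")

    def test_raising_threshold_never_increases_counts(self, vocab):
        merged = _tf_enrichment_fixture(vocab)
        counts = []
        for cutoff in (0.1, 1.0, 2.9, 3.5):
            (row,) = tf_regulated_high_counts(
                merged, "TF_X", ThresholdConfig(high_expression_min=cutoff)
            )
            counts.append(row.high_regulated_count)
        assert counts == sorted(counts, reverse=True)


class TestTfPathwayRatio:
    def test_planted_ratio(self, vocab):
        merged = _tf_enrichment_fixture(vocab)
        # annotate: 3 of the 4 high regulated genes to apoptosis, 2 to proliferation
        for i in (1, 2, 3):
            merged.add((refseq_uri(f"NM_{i:06d}"), vocab.participates_in, go_term_iri(APOPTOSIS_TERM)))
        for i in (3, 4):
            merged.add((refseq_uri(f"NM_{i:06d}"), vocab.participates_in, go_term_iri(PROLIFERATION_TERM)))
        (row,) = tf_pathway_ratio(merged, "TF_X", APOPTOSIS_TERM, PROLIFERATION_TERM)
        assert (row.count_a, row.count_b) == (3, 2)
        assert row.ratio == pytest.approx(1.5)

    def test_no_high_influence_genes(self, vocab):
        merged = _tf_enrichment_fixture(vocab)
        (row,) = tf_pathway_ratio(
            merged, "TF_X", APOPTOSIS_TERM, PROLIFERATION_TERM,
            ThresholdConfig(high_expression_min=100.0),
        )
        assert (row.count_a, row.count_b, row.ratio) == (0, 0, 0.0)


class TestStoredQueriesAgainstSetLogic:
    def test_pathway_query_equals_strict_counts(self, small_graph):
        rows = run_sparql(small_graph, PATHWAY_CONTRAST_QUERY)
        engine = sorted((str(r["sampName"]), int(r["apopcount"]), float(r["ratio"])) for r in rows)
        logic = sorted(
            (r.sample_title, r.count_a, r.ratio)
            for r in pathway_contrast_counts(
                small_graph, APOPTOSIS_TERM, PROLIFERATION_TERM, mode="strict"
            )
        )
        assert [e[:2] for e in engine] == [l[:2] for l in logic]
        for e, l in zip(engine, logic):
            assert e[2] == pytest.approx(l[2], abs=1e-9)

    def test_tf_query_equals_tf_candidates(self, small_graph, vocab):
        rows = run_sparql(small_graph, TF_CANDIDATE_QUERY)
        titles = {
            s: str(next(small_graph.objects(s, vocab.dc_title)))
            for s in small_graph.subjects(vocab.rdf_type, vocab.cell_culture)
        }
        engine = sorted(
            (str(r["rep"]), str(r["tf"]), titles[r["samp"]], float(r["obsVal"]), float(r["obsVal2"]))
            for r in rows
        )
        logic = sorted(
            (str(r.reporter), str(r.tf), r.sample_title, r.methylation_value, r.ratio_value)
            for r in tf_candidates(small_graph)
        )
        assert engine == logic
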