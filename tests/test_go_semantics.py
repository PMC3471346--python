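"""OBO parsing, SKOS conversion, annotation mapping and propagation."""

import numpy as np
import pytest
from rdflib import Graph, URIRef

from oracles import bfs_ancestors, expected_entailed_annotations, random_dag
from semomics.go_semantics import (
    CyclicHierarchyError,
    GafRecord,
    ancestors,
    annotations_to_rdf,
    aspect_property,
    entail_go,
    go_term_iri,
    parse_gaf,
    parse_obo,
    to_skos,
)
from semomics.observation_store import refseq_uri
from semomics.rdf_core import make_vocabulary

APOPTOSIS = "GO:0006915"
CELL_DEATH = "GO:0008219"
ROOT = "GO:0008150"


class TestParseObo:
    def test_empty_file_gives_empty_scheme(self):
        scheme = parse_obo("format-version: 1.2\n")
        assert scheme.terms == {} and scheme.broader_edges == frozenset()

    def test_three_term_chain(self, chain_obo):
        scheme = parse_obo(chain_obo)
        assert set(scheme.terms) == {APOPTOSIS, CELL_DEATH, ROOT}
        assert scheme.broader_edges == frozenset({(APOPTOSIS, CELL_DEATH), (CELL_DEATH, ROOT)})
        assert scheme.terms[APOPTOSIS].name == "apoptotic process"

    def test_obsolete_terms_excluded(self, chain_obo):
        obsolete = (
            "\n[Term]\nid: GO:0000099\nname: gone\nnamespace: biological_process\n"
            "is_a: GO:0008150 ! biological process\nis_obsolete: true\n"
        )
        scheme = parse_obo(chain_obo + obsolete)
        assert "GO:0000099" not in scheme.terms
        assert all("GO:0000099" not in e for e in scheme.broader_edges)

    def test_non_is_a_relationships_ignored(self, chain_obo):
        extra = (
            "\n[Term]\nid: GO:0000050\nname: part\nnamespace: biological_process\n"
            "relationship: part_of GO:0008150 ! biological process\n"
        )
        scheme = parse_obo(chain_obo + extra)
        assert "GO:0000050" in scheme.terms
        assert all(e[0] != "GO:0000050" for e in scheme.broader_edges)

    def test_cycle_raises_with_cycle_listed(self):
        cyclic = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: a\nis_a: GO:0000002\n\n"
            "[Term]\nid: GO:0000002\nname: b\nis_a: GO:0000001\n"
        )
        with pytest.raises(CyclicHierarchyError, match="GO:000000"):
            parse_obo(cyclic)


class TestToSkos:
    def test_empty_scheme_gives_empty_graph(self):
        assert len(to_skos(parse_obo("format-version: 1.2\n"))) == 0

    def test_chain_counts_and_iri_dialect(self, chain_obo, vocab):
        g = to_skos(parse_obo(chain_obo))
        concepts = set(g.subjects(vocab.rdf_type, vocab.concept))
        broader = list(g.triples((None, vocab.broader, None)))
        assert len(concepts) == 3 and len(broader) == 2 and len(g) == 5
        assert str(go_term_iri(APOPTOSIS)) == "http://purl.org/obo/owl/GO#GO_0006915"
        assert go_term_iri(APOPTOSIS) in concepts


class TestAspectProperty:
    @pytest.mark.parametrize(
        "aspect,field",
        [("P", "participates_in"), ("F", "has_function"), ("C", "part_of")],
    )
    def test_mapping(self, aspect, field, vocab):
        assert aspect_property(aspect) == getattr(vocab, field)

    def test_unknown_aspect_rejected(self):
        with pytest.raises(ValueError, match="aspect"):
            aspect_property("X")


class TestAnnotationsToRdf:
    @pytest.fixture()
    def scheme(self, chain_obo):
        return parse_obo(chain_obo)

    def test_not_qualifier_contributes_nothing(self, scheme):
        rec = GafRecord(symbol="TP53", go_id=APOPTOSIS, aspect="P", qualifier="NOT")
        g = annotations_to_rdf([rec], {"TP53": {"NM_000546"}}, scheme)
        assert len(g) == 0

    def test_one_to_many_symbol_expansion(self, scheme, vocab):
        rec = GafRecord(symbol="TP53", go_id=APOPTOSIS, aspect="P")
        g = annotations_to_rdf([rec], {"TP53": {"NM_000546", "NM_011111"}}, scheme)
        assert len(list(g.triples((None, vocab.participates_in, None)))) == 2

    def test_composition_with_refseq_uri_and_term_iri(self, scheme, vocab):
        rec = GafRecord(symbol="TP53", go_id=APOPTOSIS, aspect="P")
        g = annotations_to_rdf([rec], {"TP53": {"NM_000546"}}, scheme)
        assert (refseq_uri("NM_000546"), vocab.participates_in, go_term_iri(APOPTOSIS)) in g
        assert (refseq_uri("NM_000546"), vocab.rdf_type, vocab.transcript_class) in g

    def test_unmapped_symbol_and_unknown_term_skipped(self, scheme):
        records = [
            GafRecord(symbol="NOMAP", go_id=APOPTOSIS, aspect="P"),
            GafRecord(symbol="TP53", go_id="GO:0099999", aspect="P"),
        ]
        g = annotations_to_rdf(records, {"TP53": {"NM_000546"}}, scheme)
        assert len(g) == 0


class TestParseGaf:
    def test_comments_skipped_and_fields_read(self):
        text = "!gaf-version: 2.1\nDB\tID1\tTP53\t\tGO:0006915\tREF\tIEA\t\tP\n"
        (rec,) = parse_gaf(text)
        assert rec == GafRecord(symbol="TP53", go_id="GO:0006915", aspect="P", evidence_code="IEA")

    def test_short_row_rejected(self):
        with pytest.raises(ValueError, match="column"):
            parse_gaf("DB\tID1\tTP53\n")


class TestEntailGo:
    def test_propagates_to_all_ancestors(self, chain_obo, vocab):
        scheme = parse_obo(chain_obo)
        g = to_skos(scheme)
        gene = refseq_uri("NM_000546")
        g.add((gene, vocab.participates_in, go_term_iri(APOPTOSIS)))
        out = entail_go(g)
        assert (gene, vocab.participates_in, go_term_iri(CELL_DEATH)) in out
        assert (gene, vocab.participates_in, go_term_iri(ROOT)) in out

    def test_no_broader_edges_leaves_graph_unchanged(self, vocab):
        g = Graph()
        g.add((refseq_uri("NM_000001"), vocab.participates_in, go_term_iri(APOPTOSIS)))
        assert set(entail_go(g)) == set(g)

    def test_propagation_does_not_cross_aspects(self, chain_obo, vocab):
        scheme = parse_obo(chain_obo)
        g = to_skos(scheme)
        gene = refseq_uri("NM_000546")
        g.add((gene, vocab.participates_in, go_term_iri(APOPTOSIS)))
        out = entail_go(g)
        assert not list(out.triples((gene, vocab.has_function, None)))
        assert not list(out.triples((gene, vocab.part_of, None)))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bfs_oracle_on_random_dags(self, seed, vocab):
        rng = np.random.default_rng(seed)
        n_terms = int(rng.integers(5, 60))
        n_genes = int(rng.integers(5, 80))
        edges = random_dag(rng, n_terms)
        props = {"P": vocab.participates_in, "F": vocab.has_function, "C": vocab.part_of}
        annotations = []
        g = Graph()
        for child, parent in edges:
            g.add((go_term_iri_like(child), vocab.broader, go_term_iri_like(parent)))
        for i in range(n_genes):
            for _ in range(int(rng.integers(1, 4))):
                term = f"T{int(rng.integers(n_terms))}"
                key = str(rng.choice(list(props)))
                annotations.append((f"NM_{i:06d}", key, term))
                g.add((refseq_uri(f"NM_{i:06d}"), props[key], go_term_iri_like(term)))
        out = entail_go(g)
        got = set()
        for key, prop in props.items():
            for s, o in out.subject_objects(prop):
                got.add((str(s).split(":")[-1], key, str(o).rsplit("#", 1)[-1]))
        expected = expected_entailed_annotations(annotations, edges)
        assert got == expected
        assert set(entail_go(out)) == set(out)  # idempotence
        assert set(g) <= set(out)  # monotone


def go_term_iri_like(term: str) -> URIRef:
    return URIRef("http://purl.org/obo/owl/GO#" + term)


class TestAncestors:
    def test_root_has_no_ancestors(self, chain_obo):
        assert ancestors(parse_obo(chain_obo), ROOT) == set()

    def test_chain_ancestors(self, chain_obo):
        assert ancestors(parse_obo(chain_obo), APOPTOSIS) == {CELL_DEATH, ROOT}

    def test_unknown_term_rejected(self, chain_obo):
        with pytest.raises(ValueError, match="unknown term"):
            ancestors(parse_obo(chain_obo), "GO:0000000")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reachability_oracle_on_random_dags(self, seed):
        from semomics.go_semantics import ConceptScheme, OboTerm

        rng = np.random.default_rng(100 + seed)
        n_terms = int(rng.integers(4, 50))
        edges = set(random_dag(rng, n_terms))
        terms = {
            f"T{i}": OboTerm(id=f"T{i}", name="", namespace="biological_process")
            for i in range(n_terms)
        }
        scheme = ConceptScheme(terms=terms, broader_edges=frozenset(edges))
        oracle = bfs_ancestors(edges)
        for term in terms:
            assert ancestors(scheme, term) == oracle.get(term, set())
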