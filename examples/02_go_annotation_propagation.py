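"""GO as a SKOS concept scheme, with annotation propagation.

A gene annotated to apoptosis also participates in every broader process
(cell death, then biological process in general).  The converter expresses
GO terms as SKOS Concept instances with broader edges, and the entailment
step materializes the property chain

    participates_in o broader  ->  participates_in

to fixpoint, so queries against a general term also find genes annotated
only to its descendants.
"""

from semomics import (
    GafRecord,
    annotations_to_rdf,
    entail_go,
    go_term_iri,
    make_vocabulary,
    merge_graphs,
    parse_obo,
    to_skos,
)

OBO = """\
format-version: 1.2
ontology: demo-go

[Term]
id: GO:0008150
name: biological process
namespace: biological_process

[Term]
id: GO:0008219
name: cell death
namespace: biological_process
is_a: GO:0008150 ! biological process

[Term]
id: GO:0006915
name: apoptotic process
namespace: biological_process
is_a: GO:0008219 ! cell death
"""

vocab = make_vocabulary()
scheme = parse_obo(OBO)
annotations = annotations_to_rdf(
    [GafRecord(symbol="TP53", go_id="GO:0006915", aspect="P")],
    {"TP53": {"NM_000546"}},
    scheme,
)
graph = merge_graphs([to_skos(scheme), annotations])
entailed = entail_go(graph)

print(f"before entailment: {len(graph)} triples; after: {len(entailed)} triples")
for term in ("GO:0006915", "GO:0008219", "GO:0008150"):
    genes = list(entailed.subjects(vocab.participates_in, go_term_iri(term)))
    print(f"  genes participating in {term} ({scheme.terms[term].name}): {len(genes)}")
# The single direct annotation to apoptosis yields participation in all
# three terms: propagation follows the broader chain to the root.
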