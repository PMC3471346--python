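# Methods

## Data model

Everything is exchanged as RDF graphs with set semantics over
(subject, predicate, object) triples; rdflib supplies the container,
serialization and the SPARQL 1.1 engine. Blank nodes are never emitted:
every entity has a deterministic IRI, so merging is plain set union and
repeated runs produce identical graphs.

Observation nodes are content-addressed — the IRI is a SHA-1 hash of
(dataset title, sample title, reporter accession, measure) — which makes
graphs reproducible and gives duplicate rows a well-defined meaning: the
last row for a (dataset, sample, reporter) key wins, with a logged warning,
because every downstream analysis assumes one value per key. Dataset and
sample nodes are keyed by their (percent-encoded) titles and shared across
observations.

Measurement values are typed `xsd:double` so SPARQL `FILTER (?v > 2)`
comparisons are numeric. The stock Turtle writer renders doubles through
`%e` at six significant digits, which would corrupt values on a
serialize/parse round trip; the package registers a Turtle serializer
variant that writes doubles in quoted typed form, preserving the lexical
form (and hence all comparisons) exactly. N-Triples output is unaffected.

Borrowed vocabulary: the three terms whose numeric accessions appear in the
stored queries are fixed (IAO_0000136 *is about*, IAO_0000004 *has
measurement value*, OBI_0100060 *cell culture*). Terms known only by label
are pinned once to their canonical OBO IRIs — measurement datum IAO_0000109,
data set IAO_0000100, is quality measurement of IAO_0000221, has measurement
unit label IAO_0000039, transcript SO_0000673 — and treated as opaque
constants; nothing downstream depends on which release they came from.
`ro:part_of` deliberately serves double duty (observation→dataset membership
and cellular-component annotation), matching the query dialect; the two uses
are distinguished by subject type, never by predicate.

RefSeq accessions are normalized to versionless Bio2RDF IRIs
(`http://bio2rdf.org/refseq:NM_000546`); stripping the `.N` version suffix
maximizes joins across sources that cite different releases. This IRI is
the sole merge key between the quantitative, GO and TF models.

## GO semantics

The OBO 1.2 parser (obonet underneath) keeps only `[Term]` stanzas, drops
obsolete terms, and converts `is_a` lines to `skos:broader` edges
(child → parent); term-term `part_of`/`regulates` relationships are ignored
because only subsumption drives the propagation chain. The hierarchy must
be a DAG; a cycle aborts the build with one offending cycle listed.

Term IRIs use the legacy OBO-in-OWL dialect
`http://purl.org/obo/owl/GO#GO_0006915`, the dialect the stored queries'
`go:` prefix expects.

GAF records map genes to terms through one of three relations by aspect:
P → `ro:participates_in`, F → `has_function`, C → `ro:part_of`.
NOT-qualified records are dropped (treating a negated annotation as
positive would be wrong); evidence codes are all kept by default, with a
CLI flag for exclusion lists; one-to-many symbol→RefSeq mappings expand to
every accession, since reporters are transcript-level. Records with
unmapped symbols or terms missing from the scheme are counted and skipped.

Entailment materializes, for each relation p of the three:

    (gene, p, term), (term, broader, parent)  =>  (gene, p, parent)

to fixpoint, i.e. every annotation propagates to all ancestors of its term.
This is implemented as forward chaining with memoized ancestor sets rather
than a DL reasoner: for Horn rules of this shape the two are semantically
equivalent, and the closed graph can be queried with no reasoner in the
loop. The operation is monotone (output ⊇ input), idempotent, and never
crosses relations (a participates_in annotation never induces has_function).

## TF network semantics

Input records name a TF, the genes expressing it and the genes it
regulates. Two directly stated relations and two inferred ones describe the
network:

* `corresponds_to` is materialized in **both** directions (TF→gene and
  gene→TF). The inference chain composes it TF-first while the stored
  candidate query binds it gene-first (`?rep k:corresponds_to ?tf`); with
  both directions asserted, each consumer works. The closure join fires
  only on subjects that also carry `regulates` assertions, so the extra
  direction cannot create spurious inferences.
* `regulates` is stored TF→gene.
* `coregulates`: g1 expresses a TF that regulates g2.
* `indirectly_coregulates`: by default, every pair joined by a coregulates
  walk of length ≥ 2 — full reachability, reflecting a TF's whole sphere of
  influence over these commonly recursive, cyclic networks. A strict
  two-step variant (`indirect_depth=2`) keeps only the single chain
  application.

Cycles genuinely entail reflexive edges (a gene in a regulatory loop
indirectly coregulates itself); `allow_self=False` suppresses them in the
output for consumers that want irreflexive networks. The closure is
computed with per-node BFS reachability over the coregulates digraph;
output is a superset of the input and the operation is idempotent.

TF node IRIs percent-encode the identifier (ids like `V$HEN1_01` contain
characters illegal in IRIs) under the `k:` namespace.

## Query analysis

All thresholds are strict `>` comparisons, matching the FILTER operators of
the stored queries. Defaults: methylation > 2, expression ratio > 1 for the
pathway contrast, ratio > 0.5 for the TF-candidate scan, and ratio > 1
defining "highly expressed" for the enrichment analyses (the last is a
genuinely open choice — the two stored queries use different cutoffs in
different contexts — so it is an explicit parameter).

`pathway_contrast_counts` reports, per sample, the number of genes passing
both filters annotated (after propagation) to each of two process terms and
their ratio, with 0 reported for a zero denominator. Two row-selection
modes exist because SPARQL inner-join semantics differ from a report table:
`strict` reproduces the stored query exactly (a sample appears only when
both counts are ≥ 1 — with either count zero the query has no solutions for
that sample, so no group and no row), while `report` (the default) lists
every sample including zero rows.

`run_sparql` wraps the rdflib engine with one addition: basic graph
patterns are reordered before evaluation by greedy selectivity, using
actual store counts (per-predicate totals, distinct subject/object counts,
and exact counts for constant-bearing patterns). BGPs are conjunctions, so
reordering never changes results; without it, nested-loop evaluation of the
contrast query — whose two halves join only on the sample name, bound late
in the written order — is combinatorially infeasible even on small graphs.
The suite checks the engine route against the independent set-logic route
on every synthetic fixture.

`fisher_exact` computes the hypergeometric tail (`greater`: P(X ≥ a) with
margins fixed) or the two-sided sum of all tables whose point probability
does not exceed the observed one, entirely in exact integer arithmetic
(binomial-coefficient weights over the support, one rational division at
the end). Exactness is the point: the test suite compares against
brute-force enumeration over all tables at 1e-12 and against
scipy.stats.fisher_exact as an independent cross-check, and ties in the
two-sided tail are resolved by exact integer comparison rather than a
floating-point tolerance. Enrichment defaults to the `greater` side, the
direction of the scientific question.

The enrichment universe is the set of genes observed in the ratio dataset
for the sample under test, and "regulated by the TF" defaults to the union
of direct targets and the coregulation influence sets reached from the
genes expressing the TF (`include_influence=False` restricts to direct
targets).

## Synthetic data generator

The generator emulates the study design the analyses target: seven cell
lines (YUMAC, YUSAC2, YULAC, YUSIT1, YUGEN8 sensitive; WW165, YURIF
resistant), each measured in two datasets titled exactly "Methylation
Relative" and "AZA Pre-Post Treatment Ratios" over a shared gene universe.

* Concept DAG: one root with designated apoptosis-like and
  proliferation-like subtrees (the branch roots carry the real accessions
  GO:0008150 / GO:0006915 / GO:0008283 so the stored queries run
  unmodified); remaining terms join one branch (40/40/20
  apoptosis/proliferation/generic) with one or two parents inside it, so
  subtree membership is unambiguous. An obsolete decoy term exercises
  parser exclusion.
* Genes: RefSeq-shaped accessions (NM_ + 6 digits); defaults 420 genes, of
  which 300 are annotated within the apoptosis subtree and 60 within the
  proliferation subtree (1–3 terms per gene), the rest to generic terms. A
  small fraction of symbols (default 5%) own two accessions, exercising
  one-to-many mapping.
* TF networks: 8 TFs, each expressed by one gene and regulating 5–25; with
  probability `cycle_prob` (default 0.1) a TF additionally regulates the
  expressing gene of an earlier TF, planting cycles.
* Observations: per (sample, gene), a Bernoulli draw decides a "hit"
  (methylation > 2 **and** ratio > 1). Apoptosis-subtree genes hit at rate
  0.30 in sensitive and 0.05 in resistant samples; all other genes at the
  background rate 0.05. Hits draw values in (2.5, 8) × (1.5, 5); non-hits
  fail at least one filter, with a minority passing exactly one so
  single-filter behaviour is exercised. Values model threshold crossings
  only — there is no array-noise or probe-level physics, and no dose-response
  modelling — so passing tests demonstrate the integration and inference
  machinery, not robustness to real measurement noise.

Every stream is byte-deterministic given the configuration, and all ground
truth (ancestor sets, coregulation closures, per-sample hit sets) is
computed by independent plain set/graph code, never by the modules under
test.

## Validation and problem sizes

The acceptance suite checks: annotation propagation against a BFS ancestor
oracle on 100 random DAGs (up to 200 terms, 500 genes) with idempotence
spot-checks; the coregulation closure against a boolean matrix-power oracle
on 100 random digraphs (up to 100 genes, cycles included) under all four
depth/self-edge settings; both stored SPARQL queries against the set-logic
implementations on 25 synthetic merged graphs; Fisher exactness against
full enumeration for **every** 2×2 table with n ≤ 60 in both sidedness
modes at 1e-12; planted-label recovery (every sensitive sample outranking
every resistant one in apoptosis count) in ≥ 95% of 200 full-pipeline
replicates at the default study conditions; exact mapping triple counts and
the partition property of per-sample extraction; and monotonicity of all
analysis counts under threshold increases.

`scripts/acceptance.py` recomputes the headline quantities from scratch at
these same sizes; one run takes a few minutes, dominated by the 200
recovery replicates (each builds a ~40k-triple merged model).

## Known limitations

* The SPARQL engine is rdflib's: adequate for the fixture scale here, not a
  triple-store replacement; there is no HTTP endpoint.
* Entailment is specialized forward chaining for the specific property
  chains used, not a general OWL reasoner; other axiom types are out of
  scope.
* Only `is_a` contributes to broader edges; GO cross-products, annotation
  extensions and taxon constraints are ignored.
* The generator's two-component value distributions make threshold
  behaviour sharp by construction; analyses on real arrays would face
  boundary effects the synthetic data does not probe.
* Whether the enrichment universe should be per-sample observed genes or
  the whole genome is an open modelling choice; the implementation uses
  per-sample observed genes, the more conservative and self-contained
  option.
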