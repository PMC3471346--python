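"""The two Decitabine case-study SPARQL queries, stored as fixed text.

Both queries are kept in the exact dialect the toolkit emits so they run
unmodified over merged, entailed graphs.  Three textual repairs relative to
their typeset form were needed to make them executable and satisfiable:

* the methylation measurement-value pattern in the pathway-contrast query
  is active (``?obs obo:IAO_0000004 ?obsVal``) — without it the
  ``FILTER (?obsVal > 2)`` line refers to an unbound variable and the query
  can never match;
* the ``k:`` prefix declaration in the TF-candidate query reads ``PREFIX``;
* GO concepts use the underscore local names of the legacy OBO-in-OWL
  dialect (``go:GO_0006915``), matching the IRIs the SKOS converter emits.

The pathway-contrast query counts, per cell line, genes that were highly
methylated before demethylating treatment (relative methylation > 2) and
re-expressed afterwards (post/pre expression ratio > 1), split into an
apoptosis-annotated count and its ratio to a cell-proliferation-annotated
count.  The TF-candidate query lists genes meeting the same methylation
criterion with a relaxed expression cutoff (> 0.5) that express a
transcription factor.
"""

PATHWAY_CONTRAST_QUERY = """\
PREFIX dc: <http://purl.org/dc/elements/1.1/>
PREFIX ro: <http://www.obofoundry.org/ro/ro.owl#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX go: <http://purl.org/obo/owl/GO#>
PREFIX k: <http://krauthammerlab.med.yale.edu/>
SELECT (count (distinct ?repA) as ?apopcount) (count (distinct ?repA)/
               count (distinct ?repB) as ?ratio) ?sampName
WHERE {
   ?ds dc:title "Methylation Relative" .
   ?ds2 dc:title "AZA Pre-Post Treatment Ratios" .
   ?obs ro:part_of ?ds .
   # IAO_0000004 = 'has measurement value'
   ?obs obo:IAO_0000004 ?obsVal .
   ?obs obo:IAO_0000136 ?repA .
   ?obs obo:IAO_0000136 ?samp .
   # OBI_0100060 = 'cell culture'
   ?samp a obo:OBI_0100060 .
   ?samp dc:title ?sampName .
   # go:GO_0006915 = 'apoptosis'
   ?repA ro:participates_in go:GO_0006915 .
   ?obs2 obo:IAO_0000136 ?repA .
   ?obs2 ro:part_of ?ds2 .
   ?obs2 obo:IAO_0000004 ?obsVal2 .
   ?obs2 obo:IAO_0000136 ?samp .
   ?dsB dc:title "Methylation Relative" .
   ?dsB2 dc:title "AZA Pre-Post Treatment Ratios" .
   ?obsB ro:part_of ?dsB .
   ?obsB obo:IAO_0000004 ?obsBVal .
   ?obsB obo:IAO_0000136 ?repB .
   ?obsB obo:IAO_0000136 ?sampB .
   ?sampB a obo:OBI_0100060 .
   ?sampB dc:title ?sampName .
   # go:GO_0008283 = 'cell proliferation'
   ?repB ro:participates_in go:GO_0008283 .
   ?obs2B obo:IAO_0000136 ?repB .
   ?obs2B ro:part_of ?dsB2 .
   ?obs2B obo:IAO_0000004 ?obsBVal2 .
   ?obs2B obo:IAO_0000136 ?sampB .
   FILTER ( ?obsVal > 2) .
   FILTER ( ?obsVal2 > 1) .
   FILTER ( ?obsBVal > 2) .
   FILTER ( ?obsBVal2 > 1) .
}
GROUP BY ?sampName
ORDER BY ?sampName
"""

TF_CANDIDATE_QUERY = """\
PREFIX dc: <http://purl.org/dc/elements/1.1/>
PREFIX ro: <http://www.obofoundry.org/ro/ro.owl#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX k: <http://krauthammerlab.med.yale.edu/>
SELECT distinct ?rep ?tf ?samp ?obsVal ?obsVal2
WHERE {
   ?ds dc:title "Methylation Relative" .
   ?ds2 dc:title "AZA Pre-Post Treatment Ratios" .
   ?obs ro:part_of ?ds .
   ?obs obo:IAO_0000004 ?obsVal .
   ?obs obo:IAO_0000136 ?rep .
   ?obs obo:IAO_0000136 ?samp .
   ?samp a obo:OBI_0100060 .
   ?rep k:corresponds_to ?tf .
   ?obs2 obo:IAO_0000136 ?rep .
   ?obs2 ro:part_of ?ds2 .
   ?obs2 obo:IAO_0000004 ?obsVal2 .
   ?obs2 obo:IAO_0000136 ?samp .
   FILTER (?obsVal > 2) .
   FILTER (?obsVal2 > 0.5)
}
"""

DESCRIBE_SAMPLE_QUERY_TEMPLATE = """\
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX dc: <http://purl.org/dc/elements/1.1/>
PREFIX ro: <http://www.obofoundry.org/ro/ro.owl#>
DESCRIBE ?rep ?obs ?data ?samp
WHERE {{
   ?samp dc:title "{sample_title}".
   # IAO_0000136 = 'is_about'
   ?obs obo:IAO_0000136 ?samp.
   ?obs ro:part_of ?data.
   ?obs obo:IAO_0000136 ?rep.
}}
"""
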