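"""Map a small quantitative observation table to RDF and inspect it.

Each row of the table is one measurement (here: relative promoter
methylation) for one gene in one cell culture.  The mapping types the
observation as an IAO measurement datum, attaches the value, and links the
observation to its dataset, sample and reporter; the reporter gets a
Bio2RDF RefSeq IRI so it can merge with annotation models later.
"""

import io

from semomics import describe_sample, map_to_rdf, read_observation_table, serialize

TABLE = """\
dataset\tsample\treporter_id\treporter_title\tvalue\tmeasure\tunit
Methylation Relative\tYUMAC\tNM_000546\tTP53\t3.1\tmethylation relative\t
Methylation Relative\tYUMAC\tNM_002467\tMYC\t0.4\tmethylation relative\t
Methylation Relative\tWW165\tNM_000546\tTP53\t1.2\tmethylation relative\t
"""

records = read_observation_table(io.StringIO(TABLE))
graph = map_to_rdf(records)
print(f"{len(records)} observations -> {len(graph)} triples")

yumac = describe_sample(graph, "YUMAC")
print(f"DESCRIBE-style extraction for YUMAC: {len(yumac)} triples")
print(serialize(yumac, "turtle").decode())
# The two YUMAC observations, their values, the shared dataset node and the
# two reporter nodes; the WW165 observation is excluded.
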