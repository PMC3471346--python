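"""Transcription-factor coregulation closure over a cyclic network.

TF1 is expressed by G1 and regulates G2; TF2 is expressed by G2 and
regulates G3 and G1 (a back-edge, closing a cycle).  The closure first
derives gene-gene coregulates edges (G1 coregulates G2; G2 coregulates G3
and G1), then indirectly_coregulates for every pair joined by a coregulates
path of length >= 2 — including self-reach around the cycle.
"""

from semomics import TfRecord, entail_tf, make_vocabulary, refseq_uri, tf_to_rdf

vocab = make_vocabulary()
records = [
    TfRecord(tf_id="V$TF1_01", expressing_genes={"NM_000001"}, regulated_genes={"NM_000002"}),
    TfRecord(tf_id="V$TF2_01", expressing_genes={"NM_000002"}, regulated_genes={"NM_000003", "NM_000001"}),
]
base = tf_to_rdf(records)

for allow_self in (True, False):
    closed = entail_tf(base, allow_self=allow_self, indirect_depth="inf")
    coreg = sorted(
        (str(s).rsplit(":", 1)[-1], str(o).rsplit(":", 1)[-1])
        for s, o in closed.subject_objects(vocab.coregulates)
    )
    indirect = sorted(
        (str(s).rsplit(":", 1)[-1], str(o).rsplit(":", 1)[-1])
        for s, o in closed.subject_objects(vocab.indirectly_coregulates)
    )
    print(f"allow_self={allow_self}")
    print("  coregulates:          ", coreg)
    print("  indirectly_coregulates:", indirect)
# With self-edges allowed, the G1 -> G2 -> G1 cycle makes each gene
# indirectly coregulate itself; with allow_self=False those reflexive
# edges are suppressed in the output.
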