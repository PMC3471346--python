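"""Self-contained synthetic study fixtures with ground-truth oracles.

The generator emulates the study design the analyses were built for: seven
melanoma cell lines, five sensitive and two resistant to the demethylating
agent Decitabine, each measured in two datasets over a shared gene universe
— relative promoter methylation before treatment ("Methylation Relative")
and post/pre expression ratios after ("AZA Pre-Post Treatment Ratios").

A mini GO-style DAG contains designated apoptosis-like and proliferation-like
subtrees under one root; the planted signal is that apoptosis-subtree genes
"hit" (methylation > 2 and ratio > 1) at a higher rate in sensitive samples
(default 0.30) than in resistant ones (default 0.05, the background rate).
The generators only model threshold crossings, not array physics: hit values
are drawn clearly above both cutoffs and non-hit values below at least one.

Every emitted stream is deterministic given the configuration, parses
through the package's own readers with zero skipped records, and comes with
ground truth computed by independent plain set/graph code (never by the
modules under test).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "SyntheticConfig",
    "DagTruth",
    "AnnotationTruth",
    "TfTruth",
    "ObservationTruth",
    "GroundTruth",
    "SyntheticBundle",
    "CELL_LINE_TITLES",
    "ROOT_TERM",
    "APOPTOSIS_TERM",
    "PROLIFERATION_TERM",
    "default_sample_titles",
    "make_concept_dag",
    "make_annotations",
    "make_tf_table",
    "make_observations",
    "simulate",
    "write_bundle",
]

# The seven-cell-line design: five Decitabine-sensitive lines, two resistant.
CELL_LINE_TITLES = ("YUMAC", "YUSAC2", "YULAC", "YUSIT1", "YUGEN8", "WW165", "YURIF")
_DEFAULT_SENSITIVE = ("YUMAC", "YUSAC2", "YULAC", "YUSIT1", "YUGEN8")

# Real GO accessions for the planted roots so the stored case-study queries
# (which name apoptosis and cell proliferation) run against synthetic graphs.
ROOT_TERM = "GO:0008150"
APOPTOSIS_TERM = "GO:0006915"
PROLIFERATION_TERM = "GO:0008283"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_terms: int = 60
    n_genes: int = 420
    n_apoptosis_genes: int = 300
    n_proliferation_genes: int = 60
    n_tfs: int = 8
    n_samples: int = 7
    sensitive_samples: Optional[Tuple[str, ...]] = None
    apoptosis_hit_rate_sensitive: float = 0.30
    apoptosis_hit_rate_resistant: float = 0.05
    background_hit_rate: float = 0.05
    cycle_prob: float = 0.1
    one_to_two_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "apoptosis_hit_rate_sensitive",
            "apoptosis_hit_rate_resistant",
            "background_hit_rate",
            "cycle_prob",
            "one_to_two_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_terms < 3:
            raise ValueError("n_terms must be at least 3 (root plus two branch roots)")
        if self.n_apoptosis_genes + self.n_proliferation_genes > self.n_genes:
            raise ValueError("class gene counts exceed n_genes")
        titles = set(default_sample_titles(self.n_samples))
        for s in self.resolved_sensitive():
            if s not in titles:
                raise ValueError(f"sensitive sample {s!r} not among generated titles")

    def resolved_sensitive(self) -> Tuple[str, ...]:
        if self.sensitive_samples is not None:
            return tuple(self.sensitive_samples)
        titles = default_sample_titles(self.n_samples)
        return tuple(t for t in titles if t in _DEFAULT_SENSITIVE)


def default_sample_titles(n_samples: int) -> List[str]:
    """The seven cell-line titles, extended with SAMPLE08... beyond seven."""
    titles = list(CELL_LINE_TITLES[:n_samples])
    titles += [f"SAMPLE{i + 1:02d}" for i in range(len(titles), n_samples)]
    return titles


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


# ---------------------------------------------------------------------------
# Concept DAG
# ---------------------------------------------------------------------------


@dataclass
class DagTruth:
    term_ids: List[str]
    branch: Dict[str, str]  # term -> apoptosis | proliferation | generic | root
    edges: Set[Tuple[str, str]]  # (child, parent)
    ancestors: Dict[str, Set[str]]  # proper ancestors per term
    apoptosis_root: str = APOPTOSIS_TERM
    proliferation_root: str = PROLIFERATION_TERM
    root: str = ROOT_TERM

    def branch_terms(self, branch: str) -> List[str]:
        return sorted(t for t, b in self.branch.items() if b == branch)


def _independent_ancestors(edges: Set[Tuple[str, str]]) -> Dict[str, Set[str]]:
    """Proper-ancestor sets by plain breadth-first walk over a parent map."""
    parents: Dict[str, Set[str]] = {}
    nodes: Set[str] = set()
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        nodes.update((child, parent))
    out: Dict[str, Set[str]] = {}
    for node in nodes:
        seen: Set[str] = set()
        frontier = list(parents.get(node, ()))
        while frontier:
            cur = frontier.pop()
            if cur in seen:
                continue
            seen.add(cur)
            frontier.extend(parents.get(cur, ()))
        out[node] = seen
    return out


def make_concept_dag(cfg: SyntheticConfig) -> Tuple[str, DagTruth]:
    """Emit a rooted DAG as OBO 1.2 text plus its recorded structure.

    Terms 1-3 are the root and the apoptosis-like / proliferation-like
    branch roots (with their real GO accessions); remaining terms are
    assigned to a branch (40/40/20 apoptosis/proliferation/generic) and
    receive one or two parents within that branch, so subtree membership is
    unambiguous.  An obsolete decoy term exercises parser exclusion.
    """
    rng = _rng(cfg, 1)
    names = {
        ROOT_TERM: "biological process",
        APOPTOSIS_TERM: "apoptotic process",
        PROLIFERATION_TERM: "cell population proliferation",
    }
    branch: Dict[str, str] = {
        ROOT_TERM: "root",
        APOPTOSIS_TERM: "apoptosis",
        PROLIFERATION_TERM: "proliferation",
    }
    edges: Set[Tuple[str, str]] = {
        (APOPTOSIS_TERM, ROOT_TERM),
        (PROLIFERATION_TERM, ROOT_TERM),
    }
    term_ids: List[str] = [ROOT_TERM, APOPTOSIS_TERM, PROLIFERATION_TERM]
    parents_by_branch: Dict[str, List[str]] = {
        "apoptosis": [APOPTOSIS_TERM],
        "proliferation": [PROLIFERATION_TERM],
    }
    branch_names = {"apoptosis": "apoptotic subprocess", "proliferation": "proliferative subprocess", "generic": "generic process"}
    for i in range(3, cfg.n_terms):
        term = f"GO:{i + 1:07d}"
        if i == 3:
            b = "generic"  # guarantee at least one generic term for background genes
        else:
            b = str(rng.choice(["apoptosis", "proliferation", "generic"], p=[0.4, 0.4, 0.2]))
        branch[term] = b
        names[term] = f"{branch_names[b]} {i + 1}"
        if b == "generic":
            edges.add((term, ROOT_TERM))
        else:
            pool = parents_by_branch[b]
            n_parents = 1 + int(rng.random() < 0.3)
            chosen = rng.choice(len(pool), size=min(n_parents, len(pool)), replace=False)
            for j in sorted(int(c) for c in chosen):
                edges.add((term, pool[j]))
            pool.append(term)
        term_ids.append(term)

    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    parent_map: Dict[str, List[str]] = {}
    for child, parent in edges:
        parent_map.setdefault(child, []).append(parent)
    for term in term_ids:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {names[term]}")
        lines.append("namespace: biological_process")
        for parent in sorted(parent_map.get(term, [])):
            lines.append(f"is_a: {parent} ! {names[parent]}")
        lines.append("")
    # Obsolete decoy: must vanish during parsing and appears in no truth set.
    lines += [
        "[Term]",
        "id: GO:0999999",
        "name: obsolete decoy process",
        "namespace: biological_process",
        "is_obsolete: true",
        "",
    ]
    truth = DagTruth(
        term_ids=term_ids,
        branch=branch,
        edges=edges,
        ancestors=_independent_ancestors(edges),
    )
    return "\n".join(lines), truth


# ---------------------------------------------------------------------------
# Annotations and symbol map
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTruth:
    accessions: List[str]
    gene_class: Dict[str, str]  # accession -> apoptosis | proliferation | background
    annotations: Dict[str, Set[str]]  # accession -> direct terms
    symbol_map: Dict[str, Tuple[str, ...]]  # symbol -> accessions (1 or 2)
    gaf_row_count: int = 0


def make_annotations(cfg: SyntheticConfig, dag: DagTruth) -> Tuple[str, str, AnnotationTruth]:
    """Emit a GAF 2.1 stream and a symbol->RefSeq map with recorded truth.

    Accessions have the RefSeq lexical shape (NM_ + 6 digits).  The first
    ``n_apoptosis_genes`` accessions are annotated within the apoptosis
    subtree, the next ``n_proliferation_genes`` within the proliferation
    subtree and the rest to generic terms.  A configurable fraction of
    symbols owns two accessions of the same class (isoforms), exercising
    one-to-many symbol expansion.
    """
    rng = _rng(cfg, 2)
    accessions = [f"NM_{i + 1:06d}" for i in range(cfg.n_genes)]
    gene_class: Dict[str, str] = {}
    for i, acc in enumerate(accessions):
        if i < cfg.n_apoptosis_genes:
            gene_class[acc] = "apoptosis"
        elif i < cfg.n_apoptosis_genes + cfg.n_proliferation_genes:
            gene_class[acc] = "proliferation"
        else:
            gene_class[acc] = "background"

    pools = {
        "apoptosis": dag.branch_terms("apoptosis"),
        "proliferation": dag.branch_terms("proliferation"),
        "background": dag.branch_terms("generic") or [dag.root],
    }

    symbol_map: Dict[str, Tuple[str, ...]] = {}
    annotations: Dict[str, Set[str]] = {}
    symbol_of: Dict[str, str] = {}
    i = 0
    sym_idx = 0
    while i < len(accessions):
        sym_idx += 1
        symbol = f"SYG{sym_idx:04d}"
        acc = accessions[i]
        group = [acc]
        if (
            rng.random() < cfg.one_to_two_fraction
            and i + 1 < len(accessions)
            and gene_class[accessions[i + 1]] == gene_class[acc]
        ):
            group.append(accessions[i + 1])
        symbol_map[symbol] = tuple(group)
        pool = pools[gene_class[acc]]
        k = int(rng.integers(1, min(3, len(pool)) + 1))
        chosen = sorted(pool[int(c)] for c in rng.choice(len(pool), size=k, replace=False))
        for member in group:
            annotations[member] = set(chosen)
            symbol_of[member] = symbol
        i += len(group)

    gaf_lines = ["!gaf-version: 2.1"]
    n_rows = 0
    for symbol in symbol_map:
        acc0 = symbol_map[symbol][0]
        for term in sorted(annotations[acc0]):
            gaf_lines.append(
                "\t".join(
                    [
                        "SYNDB",
                        symbol,
                        symbol,
                        "",
                        term,
                        "SYN_REF:0000001",
                        "IEA",
                        "",
                        "P",
                        f"synthetic gene {symbol}",
                        "",
                        "gene",
                        "taxon:9606",
                        "20120125",
                        "SYN",
                        "",
                        "",
                    ]
                )
            )
            n_rows += 1
    map_lines = [f"{symbol_of[acc]}\t{acc}" for acc in accessions]
    truth = AnnotationTruth(
        accessions=accessions,
        gene_class=gene_class,
        annotations=annotations,
        symbol_map=symbol_map,
        gaf_row_count=n_rows,
    )
    return "\n".join(gaf_lines) + "\n", "\n".join(map_lines) + "\n", truth


# ---------------------------------------------------------------------------
# TF networks
# ---------------------------------------------------------------------------


@dataclass
class TfTruth:
    expressing: Dict[str, Set[str]]  # tf -> accessions expressing it
    regulated: Dict[str, Set[str]]  # tf -> direct target accessions
    coreg_edges: Set[Tuple[str, str]]  # gene -> gene coregulates
    indirect2_edges: Set[Tuple[str, str]]  # exactly-2-step walks
    indirect_inf_edges: Set[Tuple[str, str]]  # walks of length >= 2


def _closure_sets(coreg: Dict[str, Set[str]]) -> Tuple[Set[Tuple[str, str]], Set[Tuple[str, str]]]:
    """Exact-2-step and >=2-step pair sets by plain BFS (independent oracle)."""
    two: Set[Tuple[str, str]] = set()
    inf: Set[Tuple[str, str]] = set()
    reach_cache: Dict[str, Set[str]] = {}

    def reach_ge1(start: str) -> Set[str]:
        if start not in reach_cache:
            seen: Set[str] = set()
            frontier = list(coreg.get(start, ()))
            while frontier:
                node = frontier.pop()
                if node in seen:
                    continue
                seen.add(node)
                frontier.extend(coreg.get(node, ()))
            reach_cache[start] = seen
        return reach_cache[start]

    for u, mids in coreg.items():
        for v in mids:
            for w in coreg.get(v, ()):
                two.add((u, w))
            for w in reach_ge1(v):
                inf.add((u, w))
    return two, inf


def make_tf_table(cfg: SyntheticConfig, ann: AnnotationTruth) -> Tuple[str, TfTruth]:
    """Emit a TF table and record direct, two-step and full-closure sets.

    Each TF is expressed by one distinct gene and regulates 5-25 genes; with
    probability ``cycle_prob`` it additionally regulates the expressing gene
    of a previously generated TF (or its own), planting back-edges that make
    the coregulation network cyclic — as real regulatory sets are.
    """
    rng = _rng(cfg, 3)
    n = min(cfg.n_tfs, len(ann.accessions))
    tf_ids = [f"V$SYN{i + 1:02d}_01" for i in range(n)]
    expressers = [ann.accessions[int(j)] for j in rng.choice(len(ann.accessions), size=n, replace=False)]
    expressing: Dict[str, Set[str]] = {}
    regulated: Dict[str, Set[str]] = {}
    for i, tf in enumerate(tf_ids):
        expressing[tf] = {expressers[i]}
        size = int(rng.integers(5, 26))
        targets = {ann.accessions[int(j)] for j in rng.choice(len(ann.accessions), size=min(size, len(ann.accessions)), replace=False)}
        if rng.random() < cfg.cycle_prob:
            targets.add(expressers[int(rng.integers(0, i + 1))])
        regulated[tf] = targets

    coreg: Dict[str, Set[str]] = {}
    for tf in tf_ids:
        for g1 in expressing[tf]:
            coreg.setdefault(g1, set()).update(regulated[tf])
    coreg_edges = {(u, v) for u, targets in coreg.items() for v in targets}
    two, inf = _closure_sets(coreg)

    lines = ["tf_id\trole\trefseq"]
    for tf in tf_ids:
        for acc in sorted(expressing[tf]):
            lines.append(f"{tf}\texpresses\t{acc}")
        for acc in sorted(regulated[tf]):
            lines.append(f"{tf}\tregulates\t{acc}")
    truth = TfTruth(
        expressing=expressing,
        regulated=regulated,
        coreg_edges=coreg_edges,
        indirect2_edges=two,
        indirect_inf_edges=inf,
    )
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------


@dataclass
class ObservationTruth:
    sample_titles: List[str]
    labels: Dict[str, bool]  # title -> sensitive?
    hits: Dict[str, Set[str]]  # title -> accessions passing both filters
    hits_by_class: Dict[str, Dict[str, Set[str]]]


def make_observations(cfg: SyntheticConfig, ann: AnnotationTruth) -> Tuple[str, str, ObservationTruth]:
    """Emit the two observation tables with the planted sensitivity signal.

    For each (sample, gene) a Bernoulli draw decides whether the gene hits
    (methylation > 2 and ratio > 1); apoptosis-class genes use the
    sensitive/resistant rate according to the sample label, all others the
    background rate.  Hit values are drawn in (2.5, 8) x (1.5, 5); non-hits
    fail at least one filter (a minority pass exactly one, so single-filter
    behaviour is exercised).
    """
    rng = _rng(cfg, 4)
    titles = default_sample_titles(cfg.n_samples)
    sensitive = set(cfg.resolved_sensitive())
    labels = {t: t in sensitive for t in titles}
    symbol_of = {acc: sym for sym, accs in ann.symbol_map.items() for acc in accs}

    meth_lines = ["dataset\tsample\treporter_id\treporter_title\tvalue\tmeasure\tunit"]
    ratio_lines = ["dataset\tsample\treporter_id\treporter_title\tvalue\tmeasure\tunit"]
    hits: Dict[str, Set[str]] = {t: set() for t in titles}
    hits_by_class: Dict[str, Dict[str, Set[str]]] = {
        t: {"apoptosis": set(), "proliferation": set(), "background": set()} for t in titles
    }
    for title in titles:
        for acc in ann.accessions:
            cls = ann.gene_class[acc]
            if cls == "apoptosis":
                rate = cfg.apoptosis_hit_rate_sensitive if labels[title] else cfg.apoptosis_hit_rate_resistant
            else:
                rate = cfg.background_hit_rate
            hit = rng.random() < rate
            if hit:
                meth = rng.uniform(2.5, 8.0)
                ratio = rng.uniform(1.5, 5.0)
                hits[title].add(acc)
                hits_by_class[title][cls].add(acc)
            else:
                kind = rng.random()
                if kind < 0.15:  # methylated but not re-expressed
                    meth = rng.uniform(2.5, 8.0)
                    ratio = rng.uniform(0.1, 0.95)
                elif kind < 0.30:  # re-expressed but not methylated
                    meth = rng.uniform(0.2, 1.8)
                    ratio = rng.uniform(1.5, 5.0)
                else:
                    meth = rng.uniform(0.2, 1.8)
                    ratio = rng.uniform(0.1, 0.95)
            sym = symbol_of[acc]
            meth_lines.append(
                f"Methylation Relative\t{title}\t{acc}\t{sym}\t{meth:.6f}\tmethylation relative\t"
            )
            ratio_lines.append(
                f"AZA Pre-Post Treatment Ratios\t{title}\t{acc}\t{sym}\t{ratio:.6f}\texpression ratio\t"
            )
    truth = ObservationTruth(
        sample_titles=titles,
        labels=labels,
        hits=hits,
        hits_by_class=hits_by_class,
    )
    return "\n".join(meth_lines) + "\n", "\n".join(ratio_lines) + "\n", truth


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    dag: DagTruth
    annotations: AnnotationTruth
    tf: TfTruth
    observations: ObservationTruth


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    obo: str
    gaf: str
    symbol_map: str
    tf_table: str
    methylation: str
    ratios: str
    truth: GroundTruth


def simulate(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete, mutually consistent fixture set."""
    obo, dag = make_concept_dag(cfg)
    gaf, symmap, ann = make_annotations(cfg, dag)
    tf_table, tf = make_tf_table(cfg, ann)
    meth, ratios, obs = make_observations(cfg, ann)
    return SyntheticBundle(
        config=cfg,
        obo=obo,
        gaf=gaf,
        symbol_map=symmap,
        tf_table=tf_table,
        methylation=meth,
        ratios=ratios,
        truth=GroundTruth(dag=dag, annotations=ann, tf=tf, observations=obs),
    )


def write_bundle(bundle: SyntheticBundle, out_dir: Path | str) -> None:
    """Write the fixture files plus a JSON ground-truth summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "go.obo").write_text(bundle.obo)
    (out / "annotations.gaf").write_text(bundle.gaf)
    (out / "sym2refseq.tsv").write_text(bundle.symbol_map)
    (out / "tf.tsv").write_text(bundle.tf_table)
    (out / "methylation.tsv").write_text(bundle.methylation)
    (out / "ratios.tsv").write_text(bundle.ratios)
    truth = bundle.truth
    summary = {
        "config": asdict(bundle.config),
        "labels": truth.observations.labels,
        "hit_counts": {t: len(s) for t, s in truth.observations.hits.items()},
        "apoptosis_hit_counts": {
            t: len(by_cls["apoptosis"]) for t, by_cls in truth.observations.hits_by_class.items()
        },
        "n_terms": len(truth.dag.term_ids),
        "n_broader_edges": len(truth.dag.edges),
        "n_coregulates_edges": len(truth.tf.coreg_edges),
        "tf_direct_target_counts": {t: len(s) for t, s in truth.tf.regulated.items()},
    }
    (out / "truth.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
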