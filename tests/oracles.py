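"""Independent oracle implementations used by the test suite.

Everything here is deliberately written against plain Python/numpy data
structures (edge sets, adjacency matrices, factorial formulas), never
against the package's graph code paths, so each oracle provides a second,
independent route to the quantity under test.
"""

from __future__ import annotations

from math import factorial
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np


def bfs_ancestors(edges: Iterable[Tuple[str, str]]) -> Dict[str, Set[str]]:
    """Proper ancestors per node from (child, parent) edges, by BFS."""
    parents: Dict[str, Set[str]] = {}
    nodes: Set[str] = set()
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        nodes.update((child, parent))
    result: Dict[str, Set[str]] = {}
    for node in nodes:
        seen: Set[str] = set()
        queue = list(parents.get(node, ()))
        while queue:
            cur = queue.pop()
            if cur not in seen:
                seen.add(cur)
                queue.extend(parents.get(cur, ()))
        result[node] = seen
    return result


def expected_entailed_annotations(
    annotations: Iterable[Tuple[str, str, str]],
    edges: Iterable[Tuple[str, str]],
) -> Set[Tuple[str, str, str]]:
    """Expected (gene, property, term) set after propagation: each direct
    annotation plus one triple per proper ancestor of its term."""
    anc = bfs_ancestors(edges)
    out: Set[Tuple[str, str, str]] = set()
    for gene, prop, term in annotations:
        out.add((gene, prop, term))
        for ancestor in anc.get(term, ()):
            out.add((gene, prop, ancestor))
    return out


def matrix_reachability(
    nodes: Sequence[str], edges: Iterable[Tuple[str, str]]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(adjacency, >=1-step closure, >=2-step closure) boolean matrices.

    The closure is computed by repeated boolean matrix multiplication to a
    fixpoint; walks of length >= 2 are the composition of the adjacency with
    the >=1-step closure.
    """
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        adj[index[u], index[v]] = True
    closure = adj.copy()
    while True:
        new = closure | (closure @ adj)
        if (new == closure).all():
            break
        closure = new
    ge2 = adj @ closure
    return adj, closure, ge2


def coregulates_join(
    expressing: Dict[str, Set[str]], regulated: Dict[str, Set[str]]
) -> Set[Tuple[str, str]]:
    """(g1, g2) pairs sharing a TF: g1 expresses it, it regulates g2."""
    pairs: Set[Tuple[str, str]] = set()
    for tf, genes in expressing.items():
        for g1 in genes:
            for g2 in regulated.get(tf, ()):
                pairs.add((g1, g2))
    return pairs


def fisher_enumeration(a: int, b: int, c: int, d: int, sided: str) -> float:
    """Fisher p-value by brute-force enumeration of all 2x2 tables with the
    observed margins, using the factorial point-probability formula.

    Probabilities are exact integer multiples of 1/(n! / (r1! r2! c1! c2!))
    -scaled units, so the sum is exact before the single final division.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d

    def point_weight(aa: int) -> int:
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return 0
        # P = r1! r2! c1! c2! / (n! a! b! c! d!); common numerator cancels
        # in the ratio to the total, leaving integer weights below.
        return factorial(n) // (
            factorial(aa) * factorial(bb) * factorial(cc) * factorial(dd)
        )

    weights = {aa: point_weight(aa) for aa in range(0, min(r1, c1) + 1)}
    weights = {aa: w for aa, w in weights.items() if w > 0}
    total = sum(weights.values())
    observed = weights[a]
    if sided == "greater":
        numerator = sum(w for aa, w in weights.items() if aa >= a)
    else:
        numerator = sum(w for w in weights.values() if w <= observed)
    return numerator / total


def random_dag(rng: np.random.Generator, n_terms: int) -> List[Tuple[str, str]]:
    """Random rooted DAG edges (child, parent) with 1-2 parents per node."""
    edges: List[Tuple[str, str]] = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.4)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in sorted(int(x) for x in parents):
            edges.append((f"T{i}", f"T{p}"))
    return edges
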