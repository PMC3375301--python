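"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: reachability is done by
boolean matrix powers, edit distance by the textbook DP table, AUC by
exhaustive pair counting.
"""

from __future__ import annotations

import numpy as np


def reachability_closure(n: int, edges: list[tuple[int, int]], start: set[int]) -> set[int]:
    """All nodes reachable from ``start`` via ``edges``, by repeated relaxation."""
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[a, b] = True
    reach = np.zeros(n, dtype=bool)
    for s in start:
        reach[s] = True
    while True:
        new = reach | (reach @ adj)
        if (new == reach).all():
            return {int(i) for i in np.flatnonzero(reach)}
        reach = new


def edit_distance(a: str, b: str) -> int:
    """Textbook dynamic-programming Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i]
        for j, cb in enumerate(b, start=1):
            curr.append(min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = curr
    return prev[-1]


def pair_counting_auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC by exhaustive pair comparison, ties counting 1/2."""
    total = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos_scores) * len(neg_scores))


def jaccard_by_counting(a, b) -> float:
    """Jaccard index by explicit element counting (no set operators)."""
    a, b = list(a), list(b)
    inter = sum(1 for x in a if x in b)
    union_elems = []
    for x in list(a) + list(b):
        if x not in union_elems:
            union_elems.append(x)
    if not union_elems:
        return 0.0
    return inter / len(union_elems)


def random_dag_edges(n: int, rng: np.random.Generator, p: float = 0.3) -> list[tuple[int, int]]:
    """Random DAG as child->parent edges over a fixed topological order.

    Node 0 is the sole root; every other node gets at least one parent with a
    smaller index, so the graph is acyclic and single-rooted by construction.
    """
    edges = []
    for child in range(1, n):
        parents = [p_ for p_ in range(child) if rng.random() < p]
        if not parents:
            parents = [int(rng.integers(0, child))]
        edges.extend((child, parent) for parent in parents)
    return edges
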