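"""Independent brute-force oracles used to cross-check the indices.

These deliberately avoid scipy.stats.hypergeom and networkx so the checks
exercise a genuinely different computation path: literal subset enumeration
for hypergeometric tails, Floyd–Warshall on a dense matrix for shortest
paths, and direct counting for edge fractions.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def enum_hypergeom_tail(x: int, M: int, K: int, n: int) -> float:
    """P(X >= x) by exhaustive enumeration of all n-subsets of an M-set
    whose first K elements are marked.  Exact for small M."""
    if x <= 0:
        return 1.0
    hits = 0
    for subset in combinations(range(M), n):
        if sum(1 for e in subset if e < K) >= x:
            hits += 1
    return hits / comb(M, n)


def enum_overlap_counts(M: int, K: int, n: int) -> list[int]:
    """counts[x] = number of n-subsets of an M-set (first K marked) with
    exactly x marked elements, by exhaustive enumeration."""
    counts = [0] * (n + 1)
    for subset in combinations(range(M), n):
        counts[sum(1 for e in subset if e < K)] += 1
    return counts


def tails_from_counts(counts: list[int]) -> list[float]:
    """tails[x] = P(X >= x) from an exact enumeration histogram."""
    total = sum(counts)
    out = []
    acc = total
    for c in counts:
        out.append(acc / total)
        acc -= c
    out.append(0.0)  # beyond the support
    return out


def floyd_warshall_paths(nodes: list[str], edges: list[tuple[str, str]]) -> dict:
    """All-pairs shortest path lengths on an unweighted undirected graph.

    Returns {(u, v): d} for connected pairs only, u/v in either order.
    """
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    INF = np.inf
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for u, v in edges:
        d[idx[u], idx[v]] = 1.0
        d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    out = {}
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if i < j and np.isfinite(d[i, j]):
                out[(u, v)] = int(d[i, j])
                out[(v, u)] = int(d[i, j])
    return out


def edge_fraction(gene_pairs: list[tuple[str, str]],
                  edges: set[frozenset[str]],
                  nodes: set[str]) -> float | None:
    """Fraction of gene pairs (both members in `nodes`) that are edges."""
    evaluable = [(g, h) for g, h in gene_pairs if g in nodes and h in nodes]
    if not evaluable:
        return None
    return sum(1 for g, h in evaluable if frozenset((g, h)) in edges) / len(evaluable)
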