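"""TF-based performance indices (indices 1-4).

These four indices score a predicted cooperative pair from properties of the
two TFs themselves:

1. **PPI partner overlap** — how significantly the two TFs' physical
   interaction partners overlap (hypergeometric upper tail).
2. **PPI shortest path** — how close the two TFs sit in the physical PPI
   network (reciprocal of the unweighted shortest-path length).
3. **Functional similarity** — the precomputed similarity score of the two
   TFs as genes.
4. **Benchmark overlap** — list-level overlap significance between the
   algorithm's whole pair list and the gold-standard benchmark set
   (hypergeometric upper tail over all possible TF pairs).

Every index reports a non-negative, higher-is-better original score per
algorithm: significance indices use -log10(p) (with p floored at 1e-300),
the shortest-path index uses 1/d, and lookup scores are clipped below at 0.
Per-pair aggregation is the arithmetic mean over scoreable pairs; pairs the
reference data cannot score are flagged, not discarded silently.
"""

from __future__ import annotations

import logging
from math import comb, log10

import networkx as nx
from scipy import stats

from .core import IndexResult, PairScore, PredictionList, mean_of_scoreable
from .errors import ConfigError
from .reference import BenchmarkSet, GenePairScoreTable, PPINetwork

log = logging.getLogger(__name__)

P_FLOOR = 1e-300

__all__ = [
    "hypergeom_upper_tail",
    "neg_log10_p",
    "index1_partner_overlap",
    "index2_shortest_path",
    "index3_functional_similarity",
    "index4_benchmark_overlap",
]


def hypergeom_upper_tail(x: int, M: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(M, K, n), clamped to (0, 1].

    M is the universe size, K the number of marked elements, n the draw size.
    x <= 0 covers the whole support, so the tail is exactly 1.
    """
    if x <= 0:
        return 1.0
    p = float(stats.hypergeom.sf(x - 1, M, K, n))
    return min(max(p, P_FLOOR), 1.0)


def neg_log10_p(p: float) -> float:
    """-log10(p) with p floored at 1e-300 so the score stays finite."""
    return -log10(max(p, P_FLOOR))


def index1_partner_overlap(plist: PredictionList, ppi: PPINetwork) -> IndexResult:
    """Overlap significance of the two TFs' physical PPI partners.

    For a pair (A, B) with both TFs in the network, the universe is all PPI
    nodes except A and B themselves; A's partners (minus B) are the marked
    elements, B's partners (minus A) the draw, and the observed overlap
    |N(A) ∩ N(B)| is tested with a hypergeometric upper tail.  The raw score
    is -log10(p).
    """
    per_pair: list[PairScore] = []
    M = ppi.n_nodes - 2
    for pair in plist:
        if pair.a not in ppi or pair.b not in ppi:
            per_pair.append(PairScore(pair, None, "TF absent from PPI network"))
            continue
        na = ppi.neighbors(pair.a) - {pair.b}
        nb = ppi.neighbors(pair.b) - {pair.a}
        x = len(na & nb)
        p = hypergeom_upper_tail(x, M, len(na), len(nb))
        per_pair.append(
            PairScore(
                pair,
                neg_log10_p(p),
                f"|N(a)|={len(na)} |N(b)|={len(nb)} shared={x} p={p:.4g}",
            )
        )
    return mean_of_scoreable(1, per_pair)


def index2_shortest_path(
    plist: PredictionList, ppi: PPINetwork, mode: str = "reciprocal"
) -> IndexResult:
    """Proximity of the two TFs in the physical PPI network.

    The shortest-path length d >= 1 is computed by breadth-first search on
    the unweighted graph; pairs in different components are unscoreable.
    Per-pair raw score is 1/d, mapping "closer is better" onto the
    non-negative higher-is-better scale.

    ``mode`` selects the algorithm-level aggregation: ``"reciprocal"``
    (default) averages the per-pair 1/d values; ``"mean_path"`` instead
    takes the reciprocal of the mean path length.  Both orderings rank
    uniformly-close lists identically; they differ only in how heterogeneous
    path lengths are weighted.
    """
    if mode not in ("reciprocal", "mean_path"):
        raise ConfigError(f"unknown shortest-path aggregation mode: {mode!r}")
    per_pair: list[PairScore] = []
    lengths: list[int] = []
    for pair in plist:
        if pair.a not in ppi or pair.b not in ppi:
            per_pair.append(PairScore(pair, None, "TF absent from PPI network"))
            continue
        try:
            d = nx.shortest_path_length(ppi.graph, pair.a, pair.b)
        except nx.NetworkXNoPath:
            per_pair.append(PairScore(pair, None, "TFs in different components"))
            continue
        lengths.append(d)
        per_pair.append(PairScore(pair, 1.0 / d, f"d={d}"))
    result = mean_of_scoreable(2, per_pair)
    if mode == "mean_path" and lengths:
        os_val = 1.0 / (sum(lengths) / len(lengths))
        result = IndexResult(2, result.per_pair, os_val, result.n_scoreable, result.n_total)
    return result


def index3_functional_similarity(
    plist: PredictionList, funsim: GenePairScoreTable
) -> IndexResult:
    """Functional similarity of the two TFs, from the precomputed table.

    Absent pairs are unscoreable; negative table scores are clipped to 0 at
    scoring time (clip counts logged) to preserve the non-negative score
    orientation.
    """
    per_pair: list[PairScore] = []
    n_clipped = 0
    for pair in plist:
        score = funsim.lookup(pair.a, pair.b)
        if score is None:
            per_pair.append(PairScore(pair, None, "pair absent from similarity table"))
            continue
        if score < 0:
            n_clipped += 1
            score = 0.0
        per_pair.append(PairScore(pair, float(score), ""))
    if n_clipped:
        log.warning("index3: clipped %d negative similarity score(s) to 0", n_clipped)
    return mean_of_scoreable(3, per_pair)


def index4_benchmark_overlap(
    plist: PredictionList, benchmark: BenchmarkSet, tf_universe: frozenset[str] | set[str]
) -> IndexResult:
    """Overlap significance between the whole list and the benchmark set.

    With U = C(|tf_universe|, 2) possible pairs, K benchmark pairs, m list
    pairs whose TFs both lie in the universe and x of them in the benchmark,
    the upper-tail hypergeometric probability P(X >= x) is converted to the
    single list-level original score -log10(p).  Per-pair records flag each
    pair's benchmark membership (1/0), with pairs outside the universe
    unscoreable.
    """
    if len(tf_universe) < 2:
        raise ConfigError("tf_universe must contain at least 2 TFs")
    stray = benchmark.tfs - set(tf_universe)
    if stray:
        raise ConfigError(f"benchmark TFs outside tf_universe: {sorted(stray)[:5]}")
    U = comb(len(tf_universe), 2)
    K = len(benchmark)
    per_pair: list[PairScore] = []
    m = 0
    x = 0
    for pair in plist:
        if pair.a not in tf_universe or pair.b not in tf_universe:
            per_pair.append(PairScore(pair, None, "TF outside evaluation universe"))
            continue
        m += 1
        hit = pair in benchmark
        x += hit
        per_pair.append(PairScore(pair, 1.0 if hit else 0.0,
                                  "in benchmark" if hit else "not in benchmark"))
    if m == 0:
        log.warning("index4: no pair of %s lies in the TF universe", plist.name)
        os_val = 0.0
        p = 1.0
    else:
        p = hypergeom_upper_tail(x, U, K, m)
        os_val = neg_log10_p(p)
    return IndexResult(
        index_id=4,
        per_pair=tuple(per_pair),
        os=os_val,
        n_scoreable=m,
        n_total=len(per_pair),
    )
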