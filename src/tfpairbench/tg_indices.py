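"""Target-gene-based performance indices (indices 5-8).

A genuinely cooperative TF pair should co-regulate a coherent set of genes.
These indices therefore look at each pair's *common target genes* — the
intersection of the two TFs' documented regulons:

5. **Co-regulatory coefficient** — direct lookup of the pair's precomputed
   co-regulation strength.
6. **Expression coherence** — mean pairwise co-expression score over the
   common targets.
7. **Functional coherence** — mean pairwise functional-similarity score
   over the common targets.
8. **PPI coherence** — fraction of common-target gene pairs that physically
   interact.

Coherence needs at least ``min_common`` (default 2) common targets; pairs
below that, or with no gene pair covered by the reference table, are marked
unscoreable.  For regulons so large that the number of gene pairs exceeds
``max_gene_pairs``, a uniform subsample of gene pairs is scored instead; the
subsample is drawn from a per-pair RNG derived from the run seed and the TF
names, so results do not depend on list order and are reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from itertools import combinations
from math import comb
from typing import Callable, Sequence

import numpy as np

from .core import IndexResult, PairScore, PredictionList, TFPair, mean_of_scoreable
from .errors import ConfigError
from .reference import GenePairScoreTable, PPINetwork, RegulationMap
from .reference import CoregCoefficientTable

log = logging.getLogger(__name__)

__all__ = [
    "common_targets",
    "index5_coregulatory",
    "index6_expression_coherence",
    "index7_functional_coherence",
    "index8_ppi_coherence",
]


def common_targets(pair: TFPair, regmap: RegulationMap) -> frozenset[str]:
    """Intersection of the two TFs' documented target-gene sets.

    Empty if either TF is absent from the regulation map.
    """
    return regmap.targets(pair.a) & regmap.targets(pair.b)


def index5_coregulatory(
    plist: PredictionList, coreg: CoregCoefficientTable
) -> IndexResult:
    """Co-regulatory coefficient of each pair, from the precomputed table."""
    per_pair: list[PairScore] = []
    n_clipped = 0
    for pair in plist:
        value = coreg.lookup(pair)
        if value is None:
            per_pair.append(PairScore(pair, None, "pair absent from coreg table"))
            continue
        if value < 0:
            n_clipped += 1
            value = 0.0
        per_pair.append(PairScore(pair, float(value), ""))
    if n_clipped:
        log.warning("index5: clipped %d negative coefficient(s) to 0", n_clipped)
    return mean_of_scoreable(5, per_pair)


def _pair_rng(seed: int, pair: TFPair) -> np.random.Generator:
    """Deterministic per-pair RNG, independent of list order."""
    digest = hashlib.sha256(f"{seed}:{pair.a}|{pair.b}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") & 0x7FFFFFFF)


def _unrank_pair(idx: int, n: int) -> tuple[int, int]:
    """Map a flat index in [0, C(n,2)) to the idx-th unordered (i, j), i<j,
    in lexicographic order."""
    i = 0
    remaining = idx
    row = n - 1
    while remaining >= row:
        remaining -= row
        i += 1
        row -= 1
    return i, i + 1 + remaining


def _sample_gene_pairs(
    genes: Sequence[str], max_gene_pairs: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """All unordered gene pairs, or a uniform subsample of max_gene_pairs."""
    n = len(genes)
    total = comb(n, 2)
    if total <= max_gene_pairs:
        return list(combinations(genes, 2))
    picks = rng.choice(total, size=max_gene_pairs, replace=False)
    out = []
    for flat in sorted(int(k) for k in picks):
        i, j = _unrank_pair(flat, n)
        out.append((genes[i], genes[j]))
    return out


def _coherence(
    plist: PredictionList,
    regmap: RegulationMap,
    index_id: int,
    min_common: int,
    max_gene_pairs: int,
    seed: int,
    score_gene_pairs: Callable[[list[tuple[str, str]]], tuple[float | None, str]],
) -> IndexResult:
    if min_common < 2:
        raise ConfigError("min_common must be >= 2")
    if max_gene_pairs < 1:
        raise ConfigError("max_gene_pairs must be >= 1")
    per_pair: list[PairScore] = []
    for pair in plist:
        T = sorted(common_targets(pair, regmap))
        if len(T) < min_common:
            per_pair.append(
                PairScore(pair, None, f"only {len(T)} common target(s)",
                          n_common_targets=len(T))
            )
            continue
        gene_pairs = _sample_gene_pairs(T, max_gene_pairs, _pair_rng(seed, pair))
        raw, detail = score_gene_pairs(gene_pairs)
        per_pair.append(
            PairScore(pair, raw, f"n_common={len(T)} {detail}",
                      n_common_targets=len(T))
        )
    return mean_of_scoreable(index_id, per_pair)


def _table_coherence(
    table: GenePairScoreTable,
) -> Callable[[list[tuple[str, str]]], tuple[float | None, str]]:
    def score(gene_pairs: list[tuple[str, str]]) -> tuple[float | None, str]:
        values = []
        for g, h in gene_pairs:
            v = table.lookup(g, h)
            if v is not None:
                values.append(max(v, 0.0))
        if not values:
            return None, "no gene pair covered by score table"
        return float(np.mean(values)), f"scored_pairs={len(values)}/{len(gene_pairs)}"

    return score


def index6_expression_coherence(
    plist: PredictionList,
    coexp: GenePairScoreTable,
    regmap: RegulationMap,
    min_common: int = 2,
    max_gene_pairs: int = 1000,
    seed: int = 0,
) -> IndexResult:
    """Expression coherence of each pair's common targets: mean pairwise
    co-expression score over the (sub)sampled common-target gene pairs."""
    return _coherence(plist, regmap, 6, min_common, max_gene_pairs, seed,
                      _table_coherence(coexp))


def index7_functional_coherence(
    plist: PredictionList,
    funsim: GenePairScoreTable,
    regmap: RegulationMap,
    min_common: int = 2,
    max_gene_pairs: int = 1000,
    seed: int = 0,
) -> IndexResult:
    """Functional coherence of each pair's common targets: mean pairwise
    functional-similarity score, same contract as expression coherence."""
    return _coherence(plist, regmap, 7, min_common, max_gene_pairs, seed,
                      _table_coherence(funsim))


def index8_ppi_coherence(
    plist: PredictionList,
    ppi: PPINetwork,
    regmap: RegulationMap,
    min_common: int = 2,
    max_gene_pairs: int = 1000,
    seed: int = 0,
) -> IndexResult:
    """Physical PPI coherence of each pair's common targets.

    The raw score is the fraction of evaluated common-target gene pairs
    (both genes present in the PPI network) that are edges of the network;
    gene pairs with either gene outside the network are excluded from the
    denominator, and a pair with no evaluable gene pair is unscoreable.
    """

    def score(gene_pairs: list[tuple[str, str]]) -> tuple[float | None, str]:
        evaluable = [(g, h) for g, h in gene_pairs if g in ppi and h in ppi]
        if not evaluable:
            return None, "no common-target gene pair inside PPI network"
        n_edges = sum(1 for g, h in evaluable if ppi.has_edge(g, h))
        return n_edges / len(evaluable), f"edges={n_edges}/{len(evaluable)}"

    return _coherence(plist, regmap, 8, min_common, max_gene_pairs, seed, score)
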