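"""Synthetic reference bundles with planted cooperative TF pairs.

The generator emulates the six reference datasets — PPI network, regulation
map, functional-similarity and co-expression score tables, co-regulatory
coefficients, and a benchmark set — at a yeast-like but desk-fast scale.
A configurable number of TF pairs is *planted* as truly cooperative: they
receive a direct PPI edge plus guaranteed shared interaction partners, an
elevated fraction of shared target genes, boosted similarity / co-expression
/ co-regulation scores (for the pair itself and for gene pairs among its
common targets), and extra PPI edges among their common targets.  The
benchmark set is the planted set, so a prediction list enriched for planted
pairs should win under every index.

All randomness flows from a single seed through a fixed sequence of
substreams (planted pairs, regulation map, PPI, functional similarity,
co-expression, co-regulation, benchmark decoupling), so bundles are
reproducible component-wise and byte-identical when rewritten.

The *null mode* (:func:`null_config`) switches off every planted signal and
replaces the benchmark by an independent random draw, giving bundles in
which nominally planted pairs are statistically indistinguishable from
background — the negative control for the scoring machinery.

The generator verifies machinery, not biology: baseline scores are bounded
Gaussian noise and the PPI graph is Erdős–Rényi, with no attempt to match
real degree or regulon-size distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil, comb

import numpy as np

from .core import PredictionList, TFPair
from .errors import ConfigError
from .reference import (
    BenchmarkSet,
    CoregCoefficientTable,
    GenePairScoreTable,
    PPINetwork,
    ReferenceBundle,
    RegulationMap,
    assemble_bundle,
)
from .tg_indices import common_targets

log = logging.getLogger(__name__)

__all__ = ["SynthConfig", "null_config", "generate_bundle", "generate_prediction_lists"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic reference-data generator.

    Defaults give a yeast-like miniature: 50 TFs among 1000 genes, a sparse
    physical PPI network, regulons of 10-30 genes, and 27 planted
    cooperative pairs (the size of the curated yeast benchmark the real
    framework evaluates against).
    """

    n_tfs: int = 50
    n_genes: int = 1000
    n_planted_pairs: int = 27
    ppi_edge_prob: float = 0.01
    targets_per_tf: tuple[int, int] = (10, 30)
    planted_target_overlap: float = 0.5
    score_noise: float = 0.15
    baseline_score: float = 0.3
    planted_score_boost: float = 0.4
    planted_ppi_neighbors: int = 3
    planted_target_edge_frac: float = 0.3
    decouple_benchmark: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_tfs < 2 or self.n_genes < self.n_tfs:
            raise ConfigError("need n_genes >= n_tfs >= 2")
        if self.n_planted_pairs > comb(self.n_tfs, 2):
            raise ConfigError("more planted pairs than possible TF pairs")
        lo, hi = self.targets_per_tf
        if not (1 <= lo <= hi):
            raise ConfigError("targets_per_tf must be a range 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ConfigError("targets_per_tf exceeds the gene pool")
        for name in ("ppi_edge_prob", "planted_target_overlap",
                     "planted_target_edge_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.planted_score_boost < 0 or self.score_noise < 0:
            raise ConfigError("score_noise and planted_score_boost must be >= 0")


def null_config(seed: int = 0, **overrides) -> SynthConfig:
    """A configuration with every planted signal switched off.

    Planted pairs receive no PPI enrichment, no forced target overlap and no
    score boost, and the benchmark is drawn independently of them, so the
    'planted' labels carry no information at all.
    """
    return SynthConfig(
        planted_target_overlap=0.0,
        planted_score_boost=0.0,
        planted_ppi_neighbors=0,
        planted_target_edge_frac=0.0,
        decouple_benchmark=True,
        seed=seed,
        **overrides,
    )


def _unrank_pair(idx: int, n: int) -> tuple[int, int]:
    i = 0
    remaining = idx
    row = n - 1
    while remaining >= row:
        remaining -= row
        i += 1
        row -= 1
    return i, i + 1 + remaining


def _sample_tf_pairs(
    tfs: list[str], k: int, rng: np.random.Generator, exclude: frozenset[TFPair] = frozenset()
) -> list[TFPair]:
    """Sample k distinct TF pairs uniformly, optionally avoiding a set."""
    total = comb(len(tfs), 2)
    if k + len(exclude) > total:
        raise ConfigError("not enough TF pairs to sample from")
    chosen: list[TFPair] = []
    seen: set[TFPair] = set(exclude)
    while len(chosen) < k:
        flat = int(rng.integers(total))
        i, j = _unrank_pair(flat, len(tfs))
        pair = TFPair(*sorted((tfs[i], tfs[j])))
        if pair in seen:
            continue
        seen.add(pair)
        chosen.append(pair)
    return chosen


def _baseline(rng: np.random.Generator, cfg: SynthConfig, boost: bool) -> float:
    v = rng.normal(cfg.baseline_score, cfg.score_noise)
    if boost:
        v += cfg.planted_score_boost
    return float(np.clip(v, 0.0, 1.0))


def generate_bundle(cfg: SynthConfig) -> tuple[ReferenceBundle, BenchmarkSet]:
    """Generate a complete reference bundle and the planted pair set.

    Returns ``(bundle, planted)``; ``bundle.benchmark`` equals ``planted``
    unless ``cfg.decouple_benchmark`` (null mode), in which case the
    benchmark is an independent uniform draw of the same size.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    (ss_planted, ss_regmap, ss_ppi, ss_funsim,
     ss_coexp, ss_coreg, ss_bench) = ss.spawn(7)

    tfs = [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    # TFs are proteins too: the PPI network spans TFs and target genes alike.
    all_nodes = tfs + genes

    planted = _sample_tf_pairs(tfs, cfg.n_planted_pairs,
                               np.random.default_rng(ss_planted))

    # --- regulation map -----------------------------------------------------
    rng = np.random.default_rng(ss_regmap)
    lo, hi = cfg.targets_per_tf
    targets: dict[str, set[str]] = {}
    for tf in tfs:
        n_t = int(rng.integers(lo, hi + 1))
        targets[tf] = set(rng.choice(genes, size=n_t, replace=False))
    if cfg.planted_target_overlap > 0:
        for pair in planted:
            ta, tb = targets[pair.a], targets[pair.b]
            k = round(cfg.planted_target_overlap * min(len(ta), len(tb)))
            if k == 0:
                continue
            shared = set(rng.choice(sorted(ta), size=k, replace=False))
            # Graft the shared genes into B's regulon, keeping its size.
            replaceable = sorted(tb - shared)
            n_drop = max(len(tb | shared) - len(tb), 0)
            dropped = set(rng.choice(replaceable, size=min(n_drop, len(replaceable)),
                                     replace=False)) if replaceable and n_drop else set()
            targets[pair.b] = (tb - dropped) | shared
    regmap = RegulationMap({tf: frozenset(t) for tf, t in targets.items()})

    # --- PPI network --------------------------------------------------------
    rng = np.random.default_rng(ss_ppi)
    n = len(all_nodes)
    edges: set[tuple[str, str]] = set()
    # Sparse Erdős–Rényi: draw the number of edges, then sample pair indices.
    total_pairs = comb(n, 2)
    n_edges = rng.binomial(total_pairs, cfg.ppi_edge_prob)
    flat = rng.choice(total_pairs, size=min(n_edges, total_pairs), replace=False)
    for k in sorted(int(f) for f in flat):
        i, j = _unrank_pair(k, n)
        u, v = sorted((all_nodes[i], all_nodes[j]))
        edges.add((u, v))
    if cfg.planted_ppi_neighbors > 0:
        for pair in planted:
            edges.add((pair.a, pair.b))
            partners = rng.choice(genes, size=cfg.planted_ppi_neighbors, replace=False)
            for g in partners:
                edges.add(tuple(sorted((pair.a, g))))  # type: ignore[arg-type]
                edges.add(tuple(sorted((pair.b, g))))  # type: ignore[arg-type]
    if cfg.planted_target_edge_frac > 0:
        for pair in planted:
            T = sorted(regmap.targets(pair.a) & regmap.targets(pair.b))
            n_pairs = comb(len(T), 2)
            if n_pairs == 0:
                continue
            n_add = ceil(cfg.planted_target_edge_frac * n_pairs)
            flat = rng.choice(n_pairs, size=n_add, replace=False)
            for k in sorted(int(f) for f in flat):
                i, j = _unrank_pair(k, len(T))
                edges.add(tuple(sorted((T[i], T[j]))))  # type: ignore[arg-type]
    ppi = PPINetwork.from_edges(edges)

    # --- gene-pair score tables --------------------------------------------
    planted_set = frozenset(planted)
    all_tf_pairs = [TFPair(*sorted((tfs[i], tfs[j])))
                    for i in range(len(tfs)) for j in range(i + 1, len(tfs))]

    def build_table(stream: np.random.SeedSequence, kind: str) -> GenePairScoreTable:
        rng = np.random.default_rng(stream)
        scores: dict[tuple[str, str], float] = {}
        # Every TF pair is scoreable (mirrors genome-wide score tables).
        for pair in all_tf_pairs:
            scores[(pair.a, pair.b)] = _baseline(rng, cfg, pair in planted_set)
        # Gene pairs among each TF pair's common targets.
        for pair in all_tf_pairs:
            T = sorted(common_targets(pair, regmap))
            boost = pair in planted_set
            for i in range(len(T)):
                for j in range(i + 1, len(T)):
                    key = GenePairScoreTable.key(T[i], T[j])
                    if key not in scores:
                        scores[key] = _baseline(rng, cfg, boost)
        return GenePairScoreTable(kind=kind, scores=scores)

    funsim = build_table(ss_funsim, "functional_similarity")
    coexp = build_table(ss_coexp, "coexpression")

    # --- co-regulatory coefficients (all TF pairs covered) ------------------
    rng = np.random.default_rng(ss_coreg)
    coreg = CoregCoefficientTable(
        {pair: _baseline(rng, cfg, pair in planted_set) for pair in all_tf_pairs}
    )

    # --- benchmark ----------------------------------------------------------
    planted_bench = BenchmarkSet(pairs=planted_set)
    if cfg.decouple_benchmark:
        rng = np.random.default_rng(ss_bench)
        independent = _sample_tf_pairs(tfs, cfg.n_planted_pairs, rng)
        benchmark = BenchmarkSet(pairs=frozenset(independent))
    else:
        benchmark = planted_bench

    bundle = assemble_bundle(
        ppi=ppi, regmap=regmap, funsim=funsim, coexp=coexp,
        coreg=coreg, benchmark=benchmark,
        meta={
            "source": "tfpairbench synthetic generator",
            "seed": cfg.seed,
            "n_tfs": cfg.n_tfs,
            "n_genes": cfg.n_genes,
            "n_planted_pairs": cfg.n_planted_pairs,
            "null_mode": bool(cfg.decouple_benchmark),
        },
    )
    return bundle, planted_bench


def generate_prediction_lists(
    bundle: ReferenceBundle,
    planted: BenchmarkSet,
    quality_levels: list[float] | tuple[float, ...],
    list_size: int,
    seed: int = 0,
) -> list[PredictionList]:
    """One prediction list per quality level q.

    A list at quality q contains ceil(q * list_size) pairs sampled from the
    planted set (capped at its size) and the remainder sampled uniformly
    from non-planted TF pairs.  Lists are named ``q0.00`` ... ``q1.00`` and
    fully determined by the seed.
    """
    tfs = sorted({tf for pair in planted.pairs for tf in pair}
                 | set(bundle.regmap.tfs))
    total = comb(len(tfs), 2)
    if list_size > total:
        raise ConfigError(f"list_size {list_size} exceeds {total} possible pairs")
    streams = np.random.SeedSequence([seed, 0xB1]).spawn(len(quality_levels))
    lists: list[PredictionList] = []
    planted_sorted = sorted(planted.pairs)
    for q, stream in zip(quality_levels, streams):
        if not 0.0 <= q <= 1.0:
            raise ConfigError(f"quality level must lie in [0, 1], got {q}")
        rng = np.random.default_rng(stream)
        n_pl = min(ceil(q * list_size), len(planted_sorted))
        picked = [planted_sorted[i]
                  for i in rng.choice(len(planted_sorted), size=n_pl, replace=False)]
        n_bg = list_size - n_pl
        background = _sample_tf_pairs(tfs, n_bg, rng, exclude=planted.pairs) if n_bg else []
        pairs = picked + background
        order = rng.permutation(len(pairs))
        lists.append(
            PredictionList(
                name=f"q{q:.2f}",
                pairs=tuple(pairs[i] for i in order),
                source="synthetic",
            )
        )
    return lists
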