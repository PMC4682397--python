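"""End-to-end comparison pipeline.

``run_comparison`` scores every algorithm's prediction list under every
selected index against one reference bundle, assembles the score matrix,
and applies both overall scores; the resulting :class:`ComparisonReport`
carries everything the report writers need (overall table, per-index
results, per-pair details, coverage, configuration echo).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import aggregation
from .core import IndexResult, PredictionList, ScoreMatrix
from .errors import BundleError, UsageError
from .reference import ReferenceBundle
from .tf_indices import (
    index1_partner_overlap,
    index2_shortest_path,
    index3_functional_similarity,
    index4_benchmark_overlap,
)
from .tg_indices import (
    index5_coregulatory,
    index6_expression_coherence,
    index7_functional_coherence,
    index8_ppi_coherence,
)

log = logging.getLogger(__name__)

ALL_INDICES = (1, 2, 3, 4, 5, 6, 7, 8)

INDEX_NAMES = {
    1: "PPI partner overlap significance",
    2: "PPI shortest path proximity",
    3: "TF functional similarity",
    4: "benchmark overlap significance",
    5: "co-regulatory coefficient",
    6: "common-target expression coherence",
    7: "common-target functional coherence",
    8: "common-target PPI coherence",
}

__all__ = ["RunConfig", "ComparisonReport", "compute_index", "run_comparison",
           "ALL_INDICES", "INDEX_NAMES"]


@dataclass(frozen=True)
class RunConfig:
    """Tunable settings of one comparison run."""

    seed: int = 0
    min_common: int = 2
    max_gene_pairs: int = 1000
    index2_mode: str = "reciprocal"  # or "mean_path"


@dataclass
class ComparisonReport:
    """Everything one comparison produced."""

    score_matrix: ScoreMatrix
    overall: list[aggregation.OverallResult]
    index_results: dict[str, dict[int, IndexResult]]  # algorithm -> index -> result
    user_algorithm: str
    primary_score: str
    config: RunConfig

    @property
    def algorithms(self) -> list[str]:
        return self.score_matrix.algorithms

    @property
    def selected_indices(self) -> list[int]:
        return self.score_matrix.indices

    def result_for(self, algorithm: str) -> aggregation.OverallResult:
        for res in self.overall:
            if res.algorithm == algorithm:
                return res
        raise KeyError(algorithm)


def compute_index(
    index_id: int,
    plist: PredictionList,
    bundle: ReferenceBundle,
    config: RunConfig,
) -> IndexResult:
    """Dispatch one prediction list to one index."""
    if index_id == 1:
        return index1_partner_overlap(plist, bundle.ppi)
    if index_id == 2:
        return index2_shortest_path(plist, bundle.ppi, mode=config.index2_mode)
    if index_id == 3:
        return index3_functional_similarity(plist, bundle.funsim)
    if index_id == 4:
        return index4_benchmark_overlap(plist, bundle.benchmark, bundle.tf_universe)
    if index_id == 5:
        return index5_coregulatory(plist, bundle.coreg)
    if index_id == 6:
        return index6_expression_coherence(
            plist, bundle.coexp, bundle.regmap,
            config.min_common, config.max_gene_pairs, config.seed)
    if index_id == 7:
        return index7_functional_coherence(
            plist, bundle.funsim, bundle.regmap,
            config.min_common, config.max_gene_pairs, config.seed)
    if index_id == 8:
        return index8_ppi_coherence(
            plist, bundle.ppi, bundle.regmap,
            config.min_common, config.max_gene_pairs, config.seed)
    raise UsageError(f"unknown index id: {index_id}")


def run_comparison(
    user_list: PredictionList,
    compared: list[PredictionList],
    bundle: ReferenceBundle,
    selected_indices: tuple[int, ...] | list[int] | None = None,
    primary_score: str = "crs",
    config: RunConfig | None = None,
) -> ComparisonReport:
    """Score the user's list against the compared lists.

    The user's list is always part of the comparison; ``selected_indices``
    defaults to all eight.  Raises :class:`UsageError` for an empty or
    unknown index selection or duplicate list names, and
    :class:`BundleError` when no algorithm has a single scoreable pair
    under any index (a total identifier-namespace mismatch).
    """
    if config is None:
        config = RunConfig()
    if selected_indices is None:
        selected_indices = ALL_INDICES
    indices = sorted(set(int(j) for j in selected_indices))
    if not indices:
        raise UsageError("at least one performance index must be selected")
    unknown = [j for j in indices if j not in ALL_INDICES]
    if unknown:
        raise UsageError(f"unknown index id(s): {unknown}")
    all_lists = [user_list] + list(compared)
    if not compared:
        raise UsageError("at least one compared prediction list is required")
    names = [pl.name for pl in all_lists]
    if len(set(names)) != len(names):
        raise UsageError(f"duplicate prediction-list names: {names}")

    index_results: dict[str, dict[int, IndexResult]] = {}
    for plist in all_lists:
        index_results[plist.name] = {
            j: compute_index(j, plist, bundle, config) for j in indices
        }

    os_matrix = np.array(
        [[index_results[name][j].os for j in indices] for name in names]
    )
    coverage = np.array(
        [[index_results[name][j].coverage for j in indices] for name in names]
    )
    if coverage.sum() == 0:
        sample_ids = sorted({tf for pl in all_lists for pair in pl for tf in pair})[:5]
        sample_ref = sorted(bundle.tf_universe)[:5]
        raise BundleError(
            "no pair of any algorithm is scoreable under any selected index; "
            f"list identifiers look like {sample_ids}, reference identifiers "
            f"look like {sample_ref} — check the identifier namespace"
        )
    sm = ScoreMatrix(algorithms=names, indices=indices, os=os_matrix,
                     coverage=coverage)
    overall = aggregation.final_ordering(sm, primary_score=primary_score)
    return ComparisonReport(
        score_matrix=sm,
        overall=overall,
        index_results=index_results,
        user_algorithm=user_list.name,
        primary_score=primary_score,
        config=config,
    )
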