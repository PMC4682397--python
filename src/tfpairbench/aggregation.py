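"""Overall performance scores over an algorithm-by-index score matrix.

Two complementary summaries turn the matrix of original scores OS_j(i) into
one ordering of algorithms:

* **Comprehensive ranking score (CRS)** — within each index, algorithms are
  ranked by original score (rank 1 = best, ties averaged); an algorithm's
  CRS is the sum of its per-index ranks.  Lower is better.

* **Comprehensive normalized score (CNS)** — each original score is divided
  by the best score in its index, NS_j(i) = OS_j(i) / max_i' OS_j(i'), so
  0 <= NS_j(i) <= 1 with NS_j(i) = 1 exactly for the per-index best
  performer; CNS(i) = sum_j NS_j(i).  Higher is better.

Both are invariant to rescaling any index column by a positive constant.
An all-zero index column would make the normalization divide by zero; such
degenerate columns get NS = 0 for every algorithm, with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ScoreMatrix
from .errors import ConfigError

log = logging.getLogger(__name__)

__all__ = [
    "OverallResult",
    "per_index_ranks",
    "comprehensive_ranking_score",
    "comprehensive_normalized_score",
    "final_ordering",
]


@dataclass(frozen=True)
class OverallResult:
    """One algorithm's per-index ranks/normalized scores and overall scores."""

    algorithm: str
    per_index_rank: dict[int, float]
    per_index_ns: dict[int, float]
    crs: float
    cns: float
    final_rank: int


def per_index_ranks(sm: ScoreMatrix) -> np.ndarray:
    """Rank algorithms within each index: rank 1 for the highest original
    score, exact ties averaged.  Returns an n x L matrix of ranks."""
    if sm.n_algorithms == 0:
        raise ConfigError("score matrix has no algorithms")
    return stats.rankdata(-sm.os, method="average", axis=0)


def comprehensive_ranking_score(ranks: np.ndarray) -> np.ndarray:
    """Sum of per-index ranks per algorithm; the smaller, the better."""
    return np.asarray(ranks, dtype=float).sum(axis=1)


def comprehensive_normalized_score(sm: ScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Max-normalize each index column and sum across indices.

    Returns ``(ns, cns)`` where ``ns[i, j] = os[i, j] / max_i' os[i', j]``
    and ``cns = ns.sum(axis=1)``.  A column whose maximum is 0 carries no
    ranking information; its normalized scores are defined as 0, with a
    warning.
    """
    if np.any(sm.os < 0):
        raise ConfigError("original scores must be non-negative")
    col_max = sm.os.max(axis=0)
    degenerate = col_max == 0
    if np.any(degenerate):
        bad = [sm.indices[j] for j in np.flatnonzero(degenerate)]
        log.warning("degenerate all-zero score column(s) for index(es) %s; "
                    "normalized scores set to 0", bad)
    safe_max = np.where(degenerate, 1.0, col_max)
    ns = sm.os / safe_max
    ns[:, degenerate] = 0.0
    return ns, ns.sum(axis=1)


def final_ordering(sm: ScoreMatrix, primary_score: str = "crs") -> list[OverallResult]:
    """Compute both overall scores and order algorithms by the chosen one.

    ``primary_score`` is ``"crs"`` (sort ascending) or ``"cns"`` (sort
    descending).  Ties on the primary score are broken by the other score,
    then by algorithm name; final ranks are assigned 1..n in sort order.
    """
    if primary_score not in ("crs", "cns"):
        raise ConfigError(f"unknown primary score: {primary_score!r}")
    ranks = per_index_ranks(sm)
    crs = comprehensive_ranking_score(ranks)
    ns, cns = comprehensive_normalized_score(sm)

    def sort_key(i: int):
        if primary_score == "crs":
            return (crs[i], -cns[i], sm.algorithms[i])
        return (-cns[i], crs[i], sm.algorithms[i])

    order = sorted(range(sm.n_algorithms), key=sort_key)
    results = []
    for final_rank, i in enumerate(order, start=1):
        results.append(
            OverallResult(
                algorithm=sm.algorithms[i],
                per_index_rank={j: float(ranks[i, k]) for k, j in enumerate(sm.indices)},
                per_index_ns={j: float(ns[i, k]) for k, j in enumerate(sm.indices)},
                crs=float(crs[i]),
                cns=float(cns[i]),
                final_rank=final_rank,
            )
        )
    return results
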