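"""Overall scores: normalization, ranking, ordering and their invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfpairbench.aggregation import (
    comprehensive_normalized_score,
    comprehensive_ranking_score,
    final_ordering,
    per_index_ranks,
)
from tfpairbench.core import ScoreMatrix
from tfpairbench.errors import ConfigError


def matrix(os, coverage=None, indices=None):
    os = np.asarray(os, dtype=float)
    n, L = os.shape
    return ScoreMatrix(
        algorithms=[f"alg{i}" for i in range(n)],
        indices=indices or list(range(1, L + 1)),
        os=os,
        coverage=np.ones((n, L)) if coverage is None else coverage,
    )


class TestRanks:
    def test_best_performer_gets_rank_one(self):
        ranks = per_index_ranks(matrix([[5.0], [3.0], [1.0]]))
        assert list(ranks[:, 0]) == [1.0, 2.0, 3.0]

    def test_ties_averaged(self):
        ranks = per_index_ranks(matrix([[4.0], [4.0], [1.0]]))
        assert list(ranks[:, 0]) == [1.5, 1.5, 3.0]

    def test_single_algorithm(self):
        assert per_index_ranks(matrix([[2.0, 7.0]])).tolist() == [[1.0, 1.0]]

    def test_rank_mass_conserved_under_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n, L = int(rng.integers(1, 12)), int(rng.integers(1, 9))
            os = rng.choice([0.0, 1.0, 2.0, 3.5], size=(n, L))  # force ties
            ranks = per_index_ranks(matrix(os))
            assert np.allclose(ranks.sum(axis=0), n * (n + 1) / 2)


class TestCRS:
    def test_sum_of_ranks(self):
        assert comprehensive_ranking_score(np.array([[1.0, 1.0, 1.0]]))[0] == 3.0
        assert comprehensive_ranking_score(np.array([[2.0, 3.0]]))[0] == 5.0

    def test_bounds_for_11_by_8(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            os = rng.uniform(0, 10, size=(11, 8))
            crs = comprehensive_ranking_score(per_index_ranks(matrix(os)))
            assert np.all(crs >= 8.0) and np.all(crs <= 88.0)


class TestCNS:
    def test_worked_example(self):
        ns, cns = comprehensive_normalized_score(matrix([[2.0, 4.0], [1.0, 4.0]]))
        assert ns.tolist() == [[1.0, 1.0], [0.5, 1.0]]
        assert cns.tolist() == [2.0, 1.5]

    def test_single_algorithm_scores_full_marks(self):
        ns, cns = comprehensive_normalized_score(matrix([[3.0, 0.2, 7.0]]))
        assert ns.tolist() == [[1.0, 1.0, 1.0]]
        assert cns[0] == 3.0

    def test_degenerate_all_zero_column(self, caplog):
        with caplog.at_level("WARNING"):
            ns, cns = comprehensive_normalized_score(matrix([[0.0, 2.0], [0.0, 1.0]]))
        assert np.all(ns[:, 0] == 0.0)
        assert "degenerate" in caplog.text

    def test_ns_one_iff_column_maximum(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            os = rng.uniform(0.01, 5, size=(6, 4))
            ns, _ = comprehensive_normalized_score(matrix(os))
            col_max = os.max(axis=0)
            assert np.array_equal(ns == 1.0, os == col_max)
            assert np.all((ns >= 0) & (ns <= 1))


class TestOrdering:
    def test_final_ranks_follow_crs(self):
        # Dominance: row 0 best everywhere, row 1 worst.
        sm = matrix([[5.0, 5.0], [1.0, 1.0], [3.0, 3.0]])
        results = final_ordering(sm, primary_score="crs")
        assert [r.algorithm for r in results] == ["alg0", "alg2", "alg1"]
        assert [r.final_rank for r in results] == [1, 2, 3]

    def test_crs_tie_broken_by_cns(self):
        # Equal CRS (ranks {1,2} each) but different CNS.
        sm = matrix([[4.0, 1.0], [2.0, 3.0]])
        results = final_ordering(sm, primary_score="crs")
        assert results[0].crs == results[1].crs == 3.0
        assert results[0].cns > results[1].cns
        assert results[0].algorithm == "alg1"

    def test_internal_consistency_of_results(self):
        rng = np.random.default_rng(9)
        sm = matrix(rng.uniform(0, 3, size=(11, 8)))
        results = final_ordering(sm, primary_score="cns")
        assert sorted(r.final_rank for r in results) == list(range(1, 12))
        for r in results:
            assert r.crs == pytest.approx(sum(r.per_index_rank.values()))
            assert r.cns == pytest.approx(sum(r.per_index_ns.values()))

    def test_unknown_primary_score_rejected(self):
        with pytest.raises(ConfigError):
            final_ordering(matrix([[1.0]]), primary_score="median")


@settings(max_examples=100, deadline=None)
@given(
    st.integers(min_value=1, max_value=8).flatmap(
        lambda n: st.tuples(
            st.lists(
                st.lists(st.integers(min_value=0, max_value=1000),
                         min_size=3, max_size=3),
                min_size=n, max_size=n),
            # Powers of two keep the rescaling exact in floating point.
            st.sampled_from([0.25, 0.5, 2.0, 8.0]),
            st.integers(min_value=0, max_value=2),
        )
    )
)
def test_scale_invariance(args):
    """Rescaling one index column by c > 0 changes no rank, NS, CRS or CNS."""
    rows, c, col = args
    os = np.asarray(rows, dtype=float) / 10.0
    sm1 = matrix(os)
    scaled = os.copy()
    scaled[:, col] *= c
    sm2 = matrix(scaled)
    assert np.allclose(per_index_ranks(sm1), per_index_ranks(sm2))
    ns1, cns1 = comprehensive_normalized_score(sm1)
    ns2, cns2 = comprehensive_normalized_score(sm2)
    assert np.allclose(ns1, ns2) and np.allclose(cns1, cns2)
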