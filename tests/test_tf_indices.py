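"""TF-based indices: worked examples, missing-data contracts, oracles."""

from __future__ import annotations

from math import comb, log10

import numpy as np
import pytest

from conftest import make_list
from oracles import enum_hypergeom_tail
from tfpairbench.core import canonicalize_pair
from tfpairbench.errors import ConfigError
from tfpairbench.reference import BenchmarkSet, PPINetwork
from tfpairbench.tf_indices import (
    hypergeom_upper_tail,
    index1_partner_overlap,
    index2_shortest_path,
    index3_functional_similarity,
    index4_benchmark_overlap,
)


class TestIndex1PartnerOverlap:
    def test_worked_example_against_enumeration(self):
        # Universe of 10 non-TF nodes; |N(A)|=4, |N(B)|=5, overlap 3.
        edges = [("A", f"U{i}") for i in (1, 2, 3, 4)]
        edges += [("B", f"U{i}") for i in (1, 2, 3, 5, 6)]
        edges += [(f"U{i}", f"U{j}") for i, j in [(7, 8), (9, 10), (7, 10)]]
        ppi = PPINetwork.from_edges(edges)
        assert ppi.n_nodes == 12
        result = index1_partner_overlap(make_list("x", ("A", "B")), ppi)
        expected_p = 66 / 252
        assert expected_p == pytest.approx(enum_hypergeom_tail(3, 10, 4, 5))
        assert result.per_pair[0].raw == pytest.approx(-log10(expected_p), abs=1e-12)
        assert result.os == pytest.approx(-log10(expected_p), abs=1e-12)

    def test_missing_tf_not_scoreable(self, tiny_ppi):
        result = index1_partner_overlap(make_list("x", ("T1", "ZZZ")), tiny_ppi)
        assert not result.per_pair[0].scoreable
        assert result.os == 0.0

    def test_zero_overlap_gives_p_one(self):
        ppi = PPINetwork.from_edges([("A", "U1"), ("A", "U2"), ("B", "U3"),
                                     ("U4", "U5")])
        result = index1_partner_overlap(make_list("x", ("A", "B")), ppi)
        assert result.per_pair[0].raw == 0.0  # p = 1 -> -log10 = 0

    def test_neighbor_of_each_other_excluded_from_universe(self):
        # A-B edge: B must not count among A's marked partners.
        ppi = PPINetwork.from_edges([("A", "B"), ("A", "U1"), ("B", "U1"),
                                     ("U2", "U3")])
        result = index1_partner_overlap(make_list("x", ("A", "B")), ppi)
        # universe = 3 non-TF nodes, K = |{U1}| = 1, n = 1, x = 1 -> p = 1/3
        assert result.per_pair[0].raw == pytest.approx(-log10(1 / 3), abs=1e-12)


class TestIndex2ShortestPath:
    def test_adjacent_path_and_disconnected(self, tiny_ppi):
        result = index2_shortest_path(
            make_list("x", ("T1", "T2"), ("T1", "T3"), ("T1", "T5")), tiny_ppi)
        raws = [ps.raw for ps in result.per_pair]
        assert raws[0] == 1.0          # direct edge
        assert raws[1] == 0.5          # T1-G1-T3
        assert raws[2] is None         # T5 in another component
        assert result.os == pytest.approx((1.0 + 0.5) / 2)

    def test_mean_path_aggregation_mode(self, tiny_ppi):
        plist = make_list("x", ("T1", "T2"), ("T1", "T3"))
        result = index2_shortest_path(plist, tiny_ppi, mode="mean_path")
        assert result.os == pytest.approx(1 / 1.5)
        with pytest.raises(ConfigError):
            index2_shortest_path(plist, tiny_ppi, mode="bogus")


class TestIndex3FunctionalSimilarity:
    def test_lookup_absence_and_mean(self, tiny_funsim):
        result = index3_functional_similarity(
            make_list("x", ("T1", "T2"), ("T2", "T3"), ("T1", "T4")), tiny_funsim)
        assert result.per_pair[0].raw == pytest.approx(0.9)
        assert result.per_pair[2].raw is None
        assert result.os == pytest.approx((0.9 + 0.2) / 2)

    def test_negative_scores_clipped_to_zero(self, tiny_funsim):
        tiny_funsim.scores[("T1", "T5")] = -0.4
        result = index3_functional_similarity(make_list("x", ("T1", "T5")),
                                              tiny_funsim)
        assert result.per_pair[0].raw == 0.0


class TestIndex4BenchmarkOverlap:
    universe = frozenset({"T1", "T2", "T3", "T4", "T5"})
    benchmark = BenchmarkSet(pairs=frozenset({
        canonicalize_pair("T1", "T2"),
        canonicalize_pair("T1", "T3"),
        canonicalize_pair("T2", "T3"),
    }))

    def test_worked_example_m4_x2(self):
        plist = make_list("x", ("T1", "T2"), ("T1", "T3"), ("T4", "T5"),
                          ("T2", "T4"))
        result = index4_benchmark_overlap(plist, self.benchmark, self.universe)
        # U=10 possible pairs, K=3, m=4, x=2 -> p = 70/210 = 1/3
        assert enum_hypergeom_tail(2, 10, 3, 4) == pytest.approx(1 / 3)
        assert result.os == pytest.approx(-log10(1 / 3), abs=1e-12)
        assert result.n_scoreable == 4
        flags = [ps.raw for ps in result.per_pair]
        assert flags == [1.0, 1.0, 0.0, 0.0]

    def test_no_overlap_gives_zero_score(self):
        plist = make_list("x", ("T4", "T5"), ("T2", "T4"))
        result = index4_benchmark_overlap(plist, self.benchmark, self.universe)
        assert result.os == 0.0

    def test_exact_benchmark_recovery_combinatorial_identity(self):
        plist = make_list("x", *[(p.a, p.b) for p in self.benchmark])
        result = index4_benchmark_overlap(plist, self.benchmark, self.universe)
        expected_p = 1 / comb(10, 3)
        assert expected_p == pytest.approx(enum_hypergeom_tail(3, 10, 3, 3), abs=1e-12)
        assert result.os == pytest.approx(-log10(expected_p), abs=1e-12)

    def test_pairs_outside_universe_excluded(self):
        plist = make_list("x", ("T1", "T2"), ("T1", "ZZ"))
        result = index4_benchmark_overlap(plist, self.benchmark, self.universe)
        assert result.n_scoreable == 1
        assert not result.per_pair[1].scoreable

    def test_monotone_in_overlap_count(self):
        # With U, K, m fixed the score strictly increases with x.
        ps = [hypergeom_upper_tail(x, 45, 5, 8) for x in range(6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestTailHelper:
    @pytest.mark.parametrize("M,K,n", [(8, 3, 4), (10, 5, 5), (12, 6, 4)])
    def test_tail_matches_enumeration(self, M, K, n):
        for x in range(n + 2):
            assert hypergeom_upper_tail(x, M, K, n) == pytest.approx(
                enum_hypergeom_tail(x, M, K, n), abs=1e-12)

    def test_tail_values_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            M = int(rng.integers(2, 30))
            K = int(rng.integers(0, M + 1))
            n = int(rng.integers(0, M + 1))
            x = int(rng.integers(0, n + 2))
            p = hypergeom_upper_tail(x, M, K, n)
            assert 0.0 < p <= 1.0
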