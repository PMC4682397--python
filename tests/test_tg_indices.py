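"""Target-gene indices: common targets, coherence scores, subsampling."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_list
from oracles import edge_fraction
from tfpairbench.core import canonicalize_pair
from tfpairbench.errors import ConfigError
from tfpairbench.reference import (
    GenePairScoreTable,
    PPINetwork,
    RegulationMap,
)
from tfpairbench.tg_indices import (
    common_targets,
    index5_coregulatory,
    index6_expression_coherence,
    index7_functional_coherence,
    index8_ppi_coherence,
)


class TestCommonTargets:
    def test_intersection(self, tiny_regmap):
        pair = canonicalize_pair("T1", "T2")
        assert common_targets(pair, tiny_regmap) == {"G2", "G3"}

    def test_absent_tf_gives_empty_set(self, tiny_regmap):
        assert common_targets(canonicalize_pair("T1", "ZZ"), tiny_regmap) == frozenset()

    def test_identical_regulons(self):
        rm = RegulationMap({"A": frozenset({"G1", "G2"}), "B": frozenset({"G1", "G2"})})
        assert common_targets(canonicalize_pair("A", "B"), rm) == {"G1", "G2"}


class TestIndex5Coregulatory:
    def test_lookup_absence_and_mean(self, tiny_coreg):
        result = index5_coregulatory(
            make_list("x", ("T1", "T2"), ("T2", "T3"), ("T1", "T5")), tiny_coreg)
        assert result.per_pair[0].raw == pytest.approx(0.7)
        assert result.per_pair[2].raw is None
        assert result.os == pytest.approx((0.7 + 0.1) / 2)


class TestCoherenceIndices:
    def test_expression_coherence_mean_of_gene_pairs(self):
        rm = RegulationMap({"A": frozenset({"G1", "G2", "G3"}),
                            "B": frozenset({"G1", "G2", "G3"})})
        coexp = GenePairScoreTable("coexpression", {
            ("G1", "G2"): 0.9, ("G1", "G3"): 0.5, ("G2", "G3"): 0.7})
        result = index6_expression_coherence(make_list("x", ("A", "B")), coexp, rm)
        assert result.per_pair[0].raw == pytest.approx(0.7)
        assert result.per_pair[0].n_common_targets == 3

    def test_below_min_common_not_scoreable(self, tiny_coexp):
        rm = RegulationMap({"A": frozenset({"G1"}), "B": frozenset({"G1", "G2"})})
        result = index6_expression_coherence(make_list("x", ("A", "B")), tiny_coexp, rm)
        assert not result.per_pair[0].scoreable

    def test_no_table_coverage_not_scoreable(self):
        rm = RegulationMap({"A": frozenset({"G8", "G9"}), "B": frozenset({"G8", "G9"})})
        coexp = GenePairScoreTable("coexpression", {("G1", "G2"): 0.5})
        result = index6_expression_coherence(make_list("x", ("A", "B")), coexp, rm)
        assert not result.per_pair[0].scoreable
        assert result.os == 0.0

    def test_functional_coherence_single_gene_pair(self, tiny_funsim):
        rm = RegulationMap({"A": frozenset({"G2", "G3"}), "B": frozenset({"G2", "G3"})})
        result = index7_functional_coherence(make_list("x", ("A", "B")), tiny_funsim, rm)
        assert result.per_pair[0].raw == pytest.approx(0.4)

    def test_os_is_mean_over_scoreable_pairs(self, tiny_coexp):
        rm = RegulationMap({
            "A": frozenset({"G5", "G6"}), "B": frozenset({"G5", "G6"}),
            "C": frozenset({"G5", "G7"}), "D": frozenset({"G5", "G7"}),
        })
        result = index6_expression_coherence(
            make_list("x", ("A", "B"), ("C", "D")), tiny_coexp, rm)
        assert result.os == pytest.approx((0.5 + 0.9) / 2)

    def test_min_common_below_two_rejected(self, tiny_coexp, tiny_regmap):
        with pytest.raises(ConfigError):
            index6_expression_coherence(make_list("x", ("T1", "T2")),
                                        tiny_coexp, tiny_regmap, min_common=1)

    def test_seed_independent_without_subsampling(self, tiny_coexp):
        rm = RegulationMap({"A": frozenset({"G5", "G6", "G7"}),
                            "B": frozenset({"G5", "G6", "G7"})})
        plist = make_list("x", ("A", "B"))
        r1 = index6_expression_coherence(plist, tiny_coexp, rm, seed=1)
        r2 = index6_expression_coherence(plist, tiny_coexp, rm, seed=99)
        assert r1.os == r2.os == pytest.approx((0.5 + 0.9 + 0.1) / 3)

    def test_subsampling_deterministic_and_order_invariant(self):
        genes = [f"G{i:02d}" for i in range(12)]
        rng = np.random.default_rng(5)
        scores = {GenePairScoreTable.key(a, b): float(rng.uniform())
                  for i, a in enumerate(genes) for b in genes[i + 1:]}
        coexp = GenePairScoreTable("coexpression", scores)
        rm = RegulationMap({t: frozenset(genes) for t in ("A", "B", "C", "D")})
        forward = make_list("x", ("A", "B"), ("C", "D"))
        backward = make_list("x", ("C", "D"), ("A", "B"))
        r1 = index6_expression_coherence(forward, coexp, rm, max_gene_pairs=10, seed=3)
        r2 = index6_expression_coherence(backward, coexp, rm, max_gene_pairs=10, seed=3)
        assert r1.os == pytest.approx(r2.os)
        raw1 = {ps.pair: ps.raw for ps in r1.per_pair}
        raw2 = {ps.pair: ps.raw for ps in r2.per_pair}
        assert raw1 == raw2
        # A different seed draws a different subsample.
        r3 = index6_expression_coherence(forward, coexp, rm, max_gene_pairs=10, seed=4)
        assert r3.os != r1.os


class TestIndex8PPICoherence:
    def test_edge_fraction_worked_example(self):
        rm = RegulationMap({"A": frozenset({"G1", "G2", "G3"}),
                            "B": frozenset({"G1", "G2", "G3"})})
        ppi = PPINetwork.from_edges([("G1", "G2"), ("G1", "X"), ("G2", "X"),
                                     ("G3", "X"), ("A", "B")])
        result = index8_ppi_coherence(make_list("x", ("A", "B")), ppi, rm)
        assert result.per_pair[0].raw == pytest.approx(1 / 3)

    def test_single_interacting_gene_pair(self):
        rm = RegulationMap({"A": frozenset({"G1", "G2"}), "B": frozenset({"G1", "G2"})})
        ppi = PPINetwork.from_edges([("G1", "G2")])
        result = index8_ppi_coherence(make_list("x", ("A", "B")), ppi, rm)
        assert result.per_pair[0].raw == 1.0

    def test_targets_outside_network_not_scoreable(self):
        rm = RegulationMap({"A": frozenset({"G8", "G9"}), "B": frozenset({"G8", "G9"})})
        ppi = PPINetwork.from_edges([("G1", "G2")])
        result = index8_ppi_coherence(make_list("x", ("A", "B")), ppi, rm)
        assert not result.per_pair[0].scoreable

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for trial in range(25):
            n_genes = int(rng.integers(2, 11))
            genes = [f"G{i}" for i in range(n_genes)]
            edges = set()
            for i in range(n_genes):
                for j in range(i + 1, n_genes):
                    if rng.uniform() < 0.4:
                        edges.add(frozenset((genes[i], genes[j])))
            in_net = {g for g in genes if any(g in e for e in edges)}
            ppi = PPINetwork.from_edges([tuple(sorted(e)) for e in edges] or [("X", "Y")])
            rm = RegulationMap({"A": frozenset(genes), "B": frozenset(genes)})
            result = index8_ppi_coherence(make_list("x", ("A", "B")), ppi, rm)
            gene_pairs = [(genes[i], genes[j]) for i in range(n_genes)
                          for j in range(i + 1, n_genes)]
            expected = edge_fraction(gene_pairs, edges, ppi.nodes)
            if expected is None:
                assert not result.per_pair[0].scoreable
            else:
                assert result.per_pair[0].raw == pytest.approx(expected, abs=1e-12)
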