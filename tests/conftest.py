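"""Shared fixtures: a tiny hand-built reference bundle and list helpers."""

from __future__ import annotations

import pytest

from tfpairbench.core import PredictionList, canonicalize_pair
from tfpairbench.reference import (
    BenchmarkSet,
    CoregCoefficientTable,
    GenePairScoreTable,
    PPINetwork,
    RegulationMap,
    assemble_bundle,
)


def make_list(name: str, *pairs: tuple[str, str], source: str = "user") -> PredictionList:
    return PredictionList(
        name=name,
        pairs=tuple(canonicalize_pair(a, b) for a, b in pairs),
        source=source,
    )


@pytest.fixture
def tiny_ppi() -> PPINetwork:
    # T1-T2 adjacent; T1..T3 share partner g1; T5 isolated from the rest.
    return PPINetwork.from_edges([
        ("T1", "T2"), ("T1", "G1"), ("T2", "G1"), ("T3", "G1"),
        ("T2", "G2"), ("T3", "G2"), ("G1", "G2"), ("T4", "G3"),
        ("T5", "G4"),
    ])


@pytest.fixture
def tiny_regmap() -> RegulationMap:
    return RegulationMap({
        "T1": frozenset({"G1", "G2", "G3"}),
        "T2": frozenset({"G2", "G3", "G4"}),
        "T3": frozenset({"G5", "G6"}),
        "T4": frozenset({"G5", "G6", "G7"}),
    })


@pytest.fixture
def tiny_funsim() -> GenePairScoreTable:
    return GenePairScoreTable(kind="functional_similarity", scores={
        ("T1", "T2"): 0.9, ("T2", "T3"): 0.2, ("T3", "T4"): 0.6,
        ("G2", "G3"): 0.4, ("G5", "G6"): 0.8,
    })


@pytest.fixture
def tiny_coexp() -> GenePairScoreTable:
    return GenePairScoreTable(kind="coexpression", scores={
        ("G2", "G3"): 0.7, ("G5", "G6"): 0.5, ("G5", "G7"): 0.9,
        ("G6", "G7"): 0.1,
    })


@pytest.fixture
def tiny_coreg() -> CoregCoefficientTable:
    return CoregCoefficientTable({
        canonicalize_pair("T1", "T2"): 0.7,
        canonicalize_pair("T2", "T3"): 0.1,
        canonicalize_pair("T3", "T4"): 0.5,
    })


@pytest.fixture
def tiny_benchmark() -> BenchmarkSet:
    return BenchmarkSet(pairs=frozenset({
        canonicalize_pair("T1", "T2"),
        canonicalize_pair("T3", "T4"),
    }))


@pytest.fixture
def tiny_bundle(tiny_ppi, tiny_regmap, tiny_funsim, tiny_coexp, tiny_coreg,
                tiny_benchmark):
    return assemble_bundle(
        ppi=tiny_ppi, regmap=tiny_regmap, funsim=tiny_funsim,
        coexp=tiny_coexp, coreg=tiny_coreg, benchmark=tiny_benchmark,
        meta={"source": "hand-built test fixture"},
    )
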