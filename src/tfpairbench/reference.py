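"""Reference datasets used by the performance indices.

Six datasets back the eight indices: an undirected physical protein-protein
interaction (PPI) network, a TF-to-target-gene regulation map, two symmetric
gene-pair score tables (functional similarity and co-expression), a table of
TF-pair co-regulatory coefficients, and a benchmark set of known cooperative
TF pairs.  All are read from plain TSV edge lists / triples so that any
database export (BioGRID-style PPI dumps, YEASTRACT-style regulation tables,
precomputed similarity matrices) can be supplied after trivial reformatting.

Score tables are sparse: a missing gene pair means "score unavailable", never
zero.  Missing data surfaces downstream as unscoreable pairs and reduced
coverage rather than silently biasing index means toward 0.

TFs and genes share one identifier namespace (TFs are genes); identifiers are
uppercased on load, matching the pair canonicalization in :mod:`.core`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import yaml

from .core import TFPair, canonicalize_pair
from .errors import BundleError, ConsistencyError, InvalidPairError, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "RegulationMap",
    "GenePairScoreTable",
    "CoregCoefficientTable",
    "BenchmarkSet",
    "ReferenceBundle",
    "load_ppi",
    "load_regulation_map",
    "load_gene_pair_scores",
    "load_coreg_table",
    "load_benchmark",
    "assemble_bundle",
    "load_bundle",
    "write_bundle",
]


def _iter_records(path: Path, n_fields: int) -> Iterator[tuple[int, list[str]]]:
    """Yield (line number, tokens) for data lines; skip blanks and comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != n_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_fields} fields, "
                    f"got {len(tokens)}: {stripped!r}"
                )
            yield lineno, tokens


def _norm(name: str) -> str:
    return name.strip().upper()


# ---------------------------------------------------------------------------
# Dataset containers
# ---------------------------------------------------------------------------


@dataclass
class PPINetwork:
    """Undirected physical PPI network without self-loops."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        n_self = 0
        for u, v in edges:
            u, v = _norm(u), _norm(v)
            if u == v:
                n_self += 1
                continue
            g.add_edge(u, v)
        if n_self:
            log.warning("dropped %d self-loop edge(s)", n_self)
        return cls(graph=g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return self.graph.has_node(node)

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def edges(self) -> list[tuple[str, str]]:
        """Canonical (sorted-within, sorted-across) edge list."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


@dataclass
class RegulationMap:
    """TF -> set of documented target genes."""

    targets_of: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for tf, targets in self.targets_of.items():
            if not targets:
                raise BundleError(f"TF {tf!r} has an empty target set")

    @property
    def tfs(self) -> set[str]:
        return set(self.targets_of)

    def targets(self, tf: str) -> frozenset[str]:
        return self.targets_of.get(tf, frozenset())

    def __len__(self) -> int:
        return len(self.targets_of)


@dataclass
class GenePairScoreTable:
    """Symmetric sparse table of gene-pair scores.

    ``kind`` distinguishes functional-similarity from co-expression tables;
    lookups are order-independent and return ``None`` for absent pairs.
    """

    kind: str  # functional_similarity | coexpression
    scores: dict[tuple[str, str], float]

    @staticmethod
    def key(a: str, b: str) -> tuple[str, str]:
        a, b = _norm(a), _norm(b)
        return (a, b) if a <= b else (b, a)

    def lookup(self, a: str, b: str) -> float | None:
        return self.scores.get(self.key(a, b))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class CoregCoefficientTable:
    """TF pair -> co-regulatory coefficient."""

    coefficients: dict[TFPair, float]

    def lookup(self, pair: TFPair) -> float | None:
        return self.coefficients.get(pair)

    def __len__(self) -> int:
        return len(self.coefficients)

    @property
    def tfs(self) -> set[str]:
        return {tf for pair in self.coefficients for tf in pair}


@dataclass(frozen=True)
class BenchmarkSet:
    """Gold-standard set of experimentally supported cooperative TF pairs."""

    pairs: frozenset[TFPair]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise BundleError("benchmark set must be non-empty")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: object) -> bool:
        return pair in self.pairs

    def __iter__(self) -> Iterator[TFPair]:
        return iter(sorted(self.pairs))

    @property
    def tfs(self) -> set[str]:
        return {tf for pair in self.pairs for tf in pair}


@dataclass
class ReferenceBundle:
    """All six reference datasets plus the evaluation TF universe.

    ``tf_universe`` — the set of TFs over which benchmark-overlap
    significance is computed — is the union of TFs appearing in the
    regulation map, the co-regulatory table and the benchmark set.
    """

    ppi: PPINetwork
    regmap: RegulationMap
    funsim: GenePairScoreTable
    coexp: GenePairScoreTable
    coreg: CoregCoefficientTable
    benchmark: BenchmarkSet
    tf_universe: frozenset[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = self.benchmark.tfs - self.tf_universe
        if missing:
            raise BundleError(f"benchmark TFs outside tf_universe: {sorted(missing)[:5]}")
        missing = self.coreg.tfs - self.tf_universe
        if missing:
            raise BundleError(f"coreg TFs outside tf_universe: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def load_ppi(path: str | Path) -> PPINetwork:
    """Load a two-column undirected edge list.

    Self-loops are dropped and duplicate edges (in either order) collapsed,
    each with a warning; an empty file is an error.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    for _lineno, tokens in _iter_records(path, 2):
        edges.append((tokens[0], tokens[1]))
    if not edges:
        raise BundleError(f"{path}: PPI edge list is empty")
    net = PPINetwork.from_edges(edges)
    n_dup = len(edges) - net.n_edges - sum(1 for u, v in edges if _norm(u) == _norm(v))
    if n_dup > 0:
        log.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    if net.n_edges == 0:
        raise BundleError(f"{path}: no valid edges after cleaning")
    return net


def load_regulation_map(path: str | Path) -> RegulationMap:
    """Load two-column (TF, target gene) regulation records."""
    path = Path(path)
    targets: dict[str, set[str]] = {}
    for _lineno, tokens in _iter_records(path, 2):
        tf, gene = _norm(tokens[0]), _norm(tokens[1])
        targets.setdefault(tf, set()).add(gene)
    if not targets:
        log.warning("%s: regulation map is empty", path)
    return RegulationMap({tf: frozenset(genes) for tf, genes in targets.items()})


def load_gene_pair_scores(path: str | Path, kind: str) -> GenePairScoreTable:
    """Load three-column (gene, gene, score) records into a symmetric table.

    Exact duplicates collapse silently; the same pair with two different
    scores is a consistency error.
    """
    path = Path(path)
    scores: dict[tuple[str, str], float] = {}
    for lineno, tokens in _iter_records(path, 3):
        try:
            value = float(tokens[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score {tokens[2]!r}") from exc
        key = GenePairScoreTable.key(tokens[0], tokens[1])
        if key in scores and scores[key] != value:
            raise ConsistencyError(
                f"{path}:{lineno}: conflicting scores for pair {key}: "
                f"{scores[key]} vs {value}"
            )
        scores[key] = value
    return GenePairScoreTable(kind=kind, scores=scores)


def load_coreg_table(path: str | Path) -> CoregCoefficientTable:
    """Load three-column (TF, TF, coefficient) co-regulatory records."""
    path = Path(path)
    coeffs: dict[TFPair, float] = {}
    for lineno, tokens in _iter_records(path, 3):
        try:
            pair = canonicalize_pair(tokens[0], tokens[1])
        except InvalidPairError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        try:
            value = float(tokens[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric coefficient {tokens[2]!r}") from exc
        if pair in coeffs and coeffs[pair] != value:
            raise ConsistencyError(
                f"{path}:{lineno}: conflicting coefficients for {pair}"
            )
        coeffs[pair] = value
    return CoregCoefficientTable(coefficients=coeffs)


def load_benchmark(path: str | Path) -> BenchmarkSet:
    """Load the two-column benchmark pair list."""
    path = Path(path)
    pairs: set[TFPair] = set()
    for lineno, tokens in _iter_records(path, 2):
        try:
            pairs.add(canonicalize_pair(tokens[0], tokens[1]))
        except InvalidPairError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not pairs:
        raise BundleError(f"{path}: benchmark set is empty")
    return BenchmarkSet(pairs=frozenset(pairs))


# ---------------------------------------------------------------------------
# Bundle assembly and (de)serialisation
# ---------------------------------------------------------------------------

_ROLES = ("ppi", "regmap", "funsim", "coexp", "coreg", "benchmark")

_ROLE_HUMAN = {
    "ppi": "PPI network",
    "regmap": "regulation map",
    "funsim": "functional-similarity table",
    "coexp": "coexpression table",
    "coreg": "co-regulatory coefficient table",
    "benchmark": "benchmark set",
}


def assemble_bundle(
    ppi: PPINetwork | None = None,
    regmap: RegulationMap | None = None,
    funsim: GenePairScoreTable | None = None,
    coexp: GenePairScoreTable | None = None,
    coreg: CoregCoefficientTable | None = None,
    benchmark: BenchmarkSet | None = None,
    meta: dict | None = None,
) -> ReferenceBundle:
    """Assemble the six components into a validated :class:`ReferenceBundle`.

    The TF universe is the union of TFs seen in the regulation map, the
    co-regulatory table and the benchmark set.  Cross-dataset identifier
    overlap statistics are logged to expose namespace mismatches early.
    """
    components = dict(ppi=ppi, regmap=regmap, funsim=funsim, coexp=coexp,
                      coreg=coreg, benchmark=benchmark)
    for role, value in components.items():
        if value is None:
            raise BundleError(f"{_ROLE_HUMAN[role]} required")
    assert regmap is not None and coreg is not None and benchmark is not None
    assert ppi is not None
    tf_universe = frozenset(regmap.tfs | coreg.tfs | benchmark.tfs)
    in_ppi = len(tf_universe & ppi.nodes)
    log.info(
        "bundle: %d TFs in universe (%d also PPI nodes), %d PPI nodes, "
        "%d funsim pairs, %d coexp pairs, %d coreg pairs, %d benchmark pairs",
        len(tf_universe), in_ppi, ppi.n_nodes,
        len(funsim), len(coexp), len(coreg), len(benchmark),  # type: ignore[arg-type]
    )
    return ReferenceBundle(
        ppi=ppi, regmap=regmap, funsim=funsim, coexp=coexp,  # type: ignore[arg-type]
        coreg=coreg, benchmark=benchmark,
        tf_universe=tf_universe, meta=dict(meta or {}),
    )


_FILENAMES = {
    "ppi": "ppi.tsv",
    "regmap": "regulation.tsv",
    "funsim": "funsim.tsv",
    "coexp": "coexp.tsv",
    "coreg": "coreg.tsv",
    "benchmark": "benchmark.tsv",
}


def write_bundle(bundle: ReferenceBundle, outdir: str | Path) -> Path:
    """Write all six components as TSV plus a ``bundle.yaml`` manifest.

    Output is fully sorted, so identical bundles serialize byte-identically.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / _FILENAMES["ppi"], "w", encoding="utf-8") as fh:
        for u, v in bundle.ppi.edges():
            fh.write(f"{u}\t{v}\n")
    with open(outdir / _FILENAMES["regmap"], "w", encoding="utf-8") as fh:
        for tf in sorted(bundle.regmap.tfs):
            for gene in sorted(bundle.regmap.targets(tf)):
                fh.write(f"{tf}\t{gene}\n")
    for role, table in (("funsim", bundle.funsim), ("coexp", bundle.coexp)):
        with open(outdir / _FILENAMES[role], "w", encoding="utf-8") as fh:
            for (a, b), score in sorted(table.scores.items()):
                fh.write(f"{a}\t{b}\t{score:.10g}\n")
    with open(outdir / _FILENAMES["coreg"], "w", encoding="utf-8") as fh:
        for pair in sorted(bundle.coreg.coefficients):
            fh.write(f"{pair.a}\t{pair.b}\t{bundle.coreg.coefficients[pair]:.10g}\n")
    with open(outdir / _FILENAMES["benchmark"], "w", encoding="utf-8") as fh:
        for pair in bundle.benchmark:
            fh.write(f"{pair.a}\t{pair.b}\n")

    manifest = {"files": dict(_FILENAMES), "meta": bundle.meta}
    manifest_path = outdir / "bundle.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def load_bundle(path: str | Path) -> ReferenceBundle:
    """Load a bundle from a ``bundle.yaml`` manifest (or its directory)."""
    path = Path(path)
    if path.is_dir():
        path = path / "bundle.yaml"
    if not path.exists():
        raise BundleError(f"bundle manifest not found: {path}")
    with open(path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "files" not in manifest:
        raise BundleError(f"{path}: malformed bundle manifest")
    base = path.parent
    files = manifest["files"]
    for role in _ROLES:
        if role not in files:
            raise BundleError(f"{path}: manifest missing role {role!r}")
    return assemble_bundle(
        ppi=load_ppi(base / files["ppi"]),
        regmap=load_regulation_map(base / files["regmap"]),
        funsim=load_gene_pair_scores(base / files["funsim"], "functional_similarity"),
        coexp=load_gene_pair_scores(base / files["coexp"], "coexpression"),
        coreg=load_coreg_table(base / files["coreg"]),
        benchmark=load_benchmark(base / files["benchmark"]),
        meta=manifest.get("meta") or {},
    )
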