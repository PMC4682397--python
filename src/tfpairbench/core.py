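"""Canonical data types shared by every performance index.

The atomic unit of evaluation is an *unordered* pair of transcription-factor
identifiers.  Identifiers are canonicalized by stripping surrounding
whitespace and uppercasing (standard yeast gene symbols are conventionally
uppercase), and the two members are stored in lexicographic order so that
``(GAL4, GAL80)`` and ``(gal80, gal4)`` denote the same pair.  Self-pairs are
invalid: cooperativity requires two distinct factors.

This module also defines the per-pair / per-algorithm score containers used
by all eight indices, and the algorithm-by-index score matrix consumed by the
overall-score aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import EmptyListError, InvalidPairError, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "TFPair",
    "PredictionList",
    "PairScore",
    "IndexResult",
    "ScoreMatrix",
    "canonicalize_pair",
    "load_prediction_list",
    "write_prediction_list",
]


@dataclass(frozen=True, order=True)
class TFPair:
    """Canonical unordered pair of TF identifiers, with ``a < b``."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if not self.a or not self.b:
            raise InvalidPairError("TF names must be non-empty")
        if self.a == self.b:
            raise InvalidPairError(f"self-pair not allowed: {self.a!r}")
        if self.a > self.b:
            raise InvalidPairError(
                f"pair not in canonical order: ({self.a!r}, {self.b!r}); "
                "construct via canonicalize_pair()"
            )

    def __iter__(self) -> Iterator[str]:
        return iter((self.a, self.b))

    def __str__(self) -> str:
        return f"{self.a}-{self.b}"


def canonicalize_pair(raw_a: str, raw_b: str) -> TFPair:
    """Normalize two raw TF names into a canonical :class:`TFPair`.

    Names are stripped of surrounding whitespace and uppercased; the
    lexicographically smaller name becomes ``a``.  Idempotent.

    Raises
    ------
    ParseError
        If either name is empty after trimming.
    InvalidPairError
        If both names canonicalize to the same identifier (self-pair).
    """
    a = raw_a.strip().upper()
    b = raw_b.strip().upper()
    if not a or not b:
        raise ParseError(f"empty TF name in pair ({raw_a!r}, {raw_b!r})")
    if a == b:
        raise InvalidPairError(f"self-pair not allowed: {a!r}")
    if a > b:
        a, b = b, a
    return TFPair(a, b)


@dataclass(frozen=True)
class PredictionList:
    """A named list of predicted cooperative TF pairs from one algorithm.

    ``line_numbers`` (parallel to ``pairs``) records the source line of each
    pair when loaded from a file, for diagnostics; empty otherwise.
    """

    name: str
    pairs: tuple[TFPair, ...]
    source: str = "user"  # user | registry | synthetic
    line_numbers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidPairError("prediction list name must be non-empty")
        if len(set(self.pairs)) != len(self.pairs):
            raise InvalidPairError(f"duplicate pairs in list {self.name!r}")
        if self.line_numbers and len(self.line_numbers) != len(self.pairs):
            raise InvalidPairError("line_numbers must parallel pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[TFPair]:
        return iter(self.pairs)

    def __contains__(self, pair: object) -> bool:
        return pair in set(self.pairs)


def load_prediction_list(path: str | Path, name: str | None = None) -> PredictionList:
    """Read a two-column TF-pair file into a :class:`PredictionList`.

    Format: one pair per line, two tokens separated by tabs or whitespace;
    lines starting with ``#`` and blank lines are ignored.  Duplicate pairs
    (after canonicalization, in either order) are dropped with a warning,
    keeping the first occurrence.

    Raises
    ------
    ParseError
        On a line with a token count other than two, naming the line.
    EmptyListError
        If the file yields zero valid pairs.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    pairs: list[TFPair] = []
    linenos: list[int] = []
    seen: set[TFPair] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 fields, got {len(tokens)}: {stripped!r}"
                )
            try:
                pair = canonicalize_pair(*tokens)
            except InvalidPairError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            pairs.append(pair)
            linenos.append(lineno)
    if n_dup:
        log.warning("%s: dropped %d duplicate pair(s)", path, n_dup)
    if not pairs:
        raise EmptyListError(f"{path}: no valid TF pairs found")
    return PredictionList(
        name=name, pairs=tuple(pairs), source="user", line_numbers=tuple(linenos)
    )


def write_prediction_list(plist: PredictionList, path: str | Path) -> None:
    """Write a prediction list back to the two-column text format."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# prediction list: {plist.name}\n")
        for pair in plist:
            fh.write(f"{pair.a}\t{pair.b}\n")


# ---------------------------------------------------------------------------
# Score containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairScore:
    """Raw score of one pair under one index.

    ``raw`` is ``None`` when the pair is not scoreable with the available
    reference data (missing TF, disconnected, no common targets, ...);
    ``detail`` is a short human-readable diagnostic.  ``n_common_targets``
    is filled by the target-gene-based indices only.
    """

    pair: TFPair
    raw: float | None
    detail: str = ""
    n_common_targets: int | None = None

    @property
    def scoreable(self) -> bool:
        return self.raw is not None


@dataclass(frozen=True)
class IndexResult:
    """Per-algorithm result of one performance index.

    ``os`` is the algorithm-level original score (non-negative, higher is
    better); by convention it is 0 when no pair is scoreable.
    """

    index_id: int
    per_pair: tuple[PairScore, ...]
    os: float
    n_scoreable: int
    n_total: int

    def __post_init__(self) -> None:
        if self.os < 0 or not np.isfinite(self.os):
            raise ValueError(f"original score must be finite and >= 0, got {self.os}")
        if self.n_scoreable > self.n_total:
            raise ValueError("n_scoreable cannot exceed n_total")
        if self.n_scoreable == 0 and self.os != 0:
            raise ValueError("os must be 0 when nothing is scoreable")

    @property
    def coverage(self) -> float:
        return self.n_scoreable / self.n_total if self.n_total else 0.0


def mean_of_scoreable(index_id: int, per_pair: Sequence[PairScore]) -> IndexResult:
    """Aggregate per-pair raw scores into an :class:`IndexResult` by the
    arithmetic mean over scoreable pairs (0 if none are scoreable)."""
    raws = [ps.raw for ps in per_pair if ps.raw is not None]
    os_val = float(np.mean(raws)) if raws else 0.0
    return IndexResult(
        index_id=index_id,
        per_pair=tuple(per_pair),
        os=os_val,
        n_scoreable=len(raws),
        n_total=len(per_pair),
    )


@dataclass
class ScoreMatrix:
    """Original scores OS_j(i) for algorithms i (rows) by indices j (cols).

    All entries are non-negative ("higher is better" orientation) — this is
    what lets max-normalization keep normalized scores inside [0, 1].
    ``coverage`` holds the fraction of each algorithm's pairs that were
    scoreable under each index.
    """

    algorithms: list[str]
    indices: list[int]
    os: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.os = np.asarray(self.os, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        n, L = len(self.algorithms), len(self.indices)
        if self.os.shape != (n, L):
            raise ValueError(f"os shape {self.os.shape} != ({n}, {L})")
        if self.coverage.shape != (n, L):
            raise ValueError(f"coverage shape {self.coverage.shape} != ({n}, {L})")
        if not np.all(np.isfinite(self.os)) or np.any(self.os < 0):
            raise ValueError("original scores must be finite and >= 0")
        if np.any(self.coverage < 0) or np.any(self.coverage > 1):
            raise ValueError("coverage values must lie in [0, 1]")
        if len(set(self.algorithms)) != n:
            raise ValueError("algorithm names must be unique")

    @property
    def n_algorithms(self) -> int:
        return len(self.algorithms)

    @property
    def n_indices(self) -> int:
        return len(self.indices)
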