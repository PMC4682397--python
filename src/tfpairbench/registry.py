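"""Metadata registry of published cooperative-TF-pair prediction algorithms.

Fifteen yeast algorithms with publicly available predicted-pair lists are
registered here with their publication label and list size.  The registry
carries metadata only — the actual pair lists are not redistributed and must
be supplied by the user as two-column text files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import BenchmarkError

__all__ = ["AlgorithmRegistryEntry", "bundled_algorithm_registry", "registry_entry",
           "write_registry_tsv"]


@dataclass(frozen=True)
class AlgorithmRegistryEntry:
    """One published prediction algorithm: display name, venue, list size."""

    name: str
    citation_label: str
    n_pctfps: int

    def __post_init__(self) -> None:
        if self.n_pctfps < 0:
            raise ValueError("list size must be non-negative")


_REGISTRY: tuple[AlgorithmRegistryEntry, ...] = (
    AlgorithmRegistryEntry("Banerjee and Zhang (NAR 2003)", "NAR 2003", 31),
    AlgorithmRegistryEntry("Harbison et al. (Nature 2004)", "Nature 2004", 94),
    AlgorithmRegistryEntry("Nagamine et al. (NAR 2005)", "NAR 2005", 24),
    AlgorithmRegistryEntry("Tsai et al. (PNAS 2005)", "PNAS 2005", 18),
    AlgorithmRegistryEntry("Chang et al. (Bioinformatics 2006)", "Bioinformatics 2006", 55),
    AlgorithmRegistryEntry("He et al. (IEEE GCCW 2006)", "IEEE GCCW 2006", 30),
    AlgorithmRegistryEntry("Yu et al. (NAR 2006)", "NAR 2006", 300),
    AlgorithmRegistryEntry("Wang J (JBI 2007)", "JBI 2007", 14),
    AlgorithmRegistryEntry("Elati et al. (Bioinformatics 2007)", "Bioinformatics 2007", 20),
    AlgorithmRegistryEntry("Datta and Zhao (Bioinformatics 2008)", "Bioinformatics 2008", 25),
    AlgorithmRegistryEntry("Chuang et al. (BMC Bioinformatics 2009)", "BMC Bioinformatics 2009", 13),
    AlgorithmRegistryEntry("Wang Y et al. (NAR 2009)", "NAR 2009", 159),
    AlgorithmRegistryEntry("Yang et al. (Cell Research 2010)", "Cell Research 2010", 186),
    AlgorithmRegistryEntry("Chen et al. (Bioinformatics 2012)", "Bioinformatics 2012", 221),
    AlgorithmRegistryEntry("Lai et al. (BMC Systems Biology 2014)", "BMC Systems Biology 2014", 27),
)


def bundled_algorithm_registry() -> tuple[AlgorithmRegistryEntry, ...]:
    """Return the 15 registered algorithms (metadata only, no pair data)."""
    return _REGISTRY


def registry_entry(name: str) -> AlgorithmRegistryEntry:
    """Look up one registry entry by its display name."""
    for entry in _REGISTRY:
        if entry.name == name:
            return entry
    raise BenchmarkError(f"unknown algorithm: {name!r}")


def write_registry_tsv(path: str | Path) -> None:
    """Export the registry as TSV (name, citation_label, n_pctfps)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tcitation_label\tn_pctfps\n")
        for entry in _REGISTRY:
            fh.write(f"{entry.name}\t{entry.citation_label}\t{entry.n_pctfps}\n")
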