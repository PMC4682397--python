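"""Report writers: TSV tables, per-pair detail files, metadata, bar charts.

One comparison run is written as::

    overall_table.tsv                     one row per algorithm, sorted by
                                          final rank: per-index original
                                          scores, ranks, normalized scores,
                                          both overall scores
    index<k>_scores.tsv                   algorithm-level table of index k
    details_index<k>_<algorithm>.txt      per-pair raw scores of index k
    run_metadata.yaml                     config echo, seed, coverage
    charts/ (optional)                    bar charts per index and overall

All writers iterate in deterministic order and use fixed float formatting,
so re-running with identical inputs reproduces byte-identical files.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import yaml

from . import __version__
from .core import IndexResult
from .pipeline import INDEX_NAMES, ComparisonReport

log = logging.getLogger(__name__)

__all__ = ["write_report"]

_FLOAT = "{:.6g}"


def _fmt(x: float | None) -> str:
    return "NA" if x is None else _FLOAT.format(x)


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name).strip("_")


def _write_overall(report: ComparisonReport, path: Path) -> None:
    indices = report.selected_indices
    cols = ["algorithm", "final_rank"]
    for j in indices:
        cols += [f"os_index{j}", f"rank_index{j}", f"ns_index{j}"]
    cols += ["crs", "cns"]
    sm = report.score_matrix
    row_of = {name: i for i, name in enumerate(sm.algorithms)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for res in report.overall:
            i = row_of[res.algorithm]
            cells = [res.algorithm, str(res.final_rank)]
            for k, j in enumerate(indices):
                cells += [
                    _fmt(float(sm.os[i, k])),
                    _fmt(res.per_index_rank[j]),
                    _fmt(res.per_index_ns[j]),
                ]
            cells += [_fmt(res.crs), _fmt(res.cns)]
            fh.write("\t".join(cells) + "\n")


def _write_index_table(report: ComparisonReport, j: int, path: Path) -> None:
    sm = report.score_matrix
    k = sm.indices.index(j)
    rows = []
    for res in report.overall:
        i = sm.algorithms.index(res.algorithm)
        ir = report.index_results[res.algorithm][j]
        rows.append((res.per_index_rank[j], res.algorithm, sm.os[i, k],
                     res.per_index_ns[j], ir))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("algorithm\tos\trank\tns\tn_scoreable\tn_total\tcoverage\n")
        for rank, name, os_val, ns, ir in rows:
            fh.write(
                f"{name}\t{_fmt(float(os_val))}\t{_fmt(rank)}\t{_fmt(ns)}\t"
                f"{ir.n_scoreable}\t{ir.n_total}\t{_fmt(ir.coverage)}\n"
            )


def _write_details(ir: IndexResult, path: Path) -> None:
    tg_based = ir.index_id in (5, 6, 7, 8)
    with open(path, "w", encoding="utf-8") as fh:
        header = "tf1\ttf2\traw_score\tscoreable"
        if tg_based:
            header += "\tn_common_targets"
        fh.write(header + "\tdetail\n")
        for ps in ir.per_pair:
            cells = [ps.pair.a, ps.pair.b, _fmt(ps.raw),
                     "yes" if ps.scoreable else "no"]
            if tg_based:
                cells.append("NA" if ps.n_common_targets is None
                             else str(ps.n_common_targets))
            cells.append(ps.detail)
            fh.write("\t".join(cells) + "\n")


def _write_metadata(report: ComparisonReport, path: Path) -> None:
    sm = report.score_matrix
    meta = {
        "tfpairbench_version": __version__,
        "user_algorithm": report.user_algorithm,
        "algorithms": list(sm.algorithms),
        "selected_indices": {j: INDEX_NAMES[j] for j in sm.indices},
        "primary_score": report.primary_score,
        "config": {
            "seed": report.config.seed,
            "min_common": report.config.min_common,
            "max_gene_pairs": report.config.max_gene_pairs,
            "index2_mode": report.config.index2_mode,
        },
        "coverage": {
            name: {j: float(sm.coverage[i, k])
                   for k, j in enumerate(sm.indices)}
            for i, name in enumerate(sm.algorithms)
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def _write_charts(report: ComparisonReport, chart_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chart_dir.mkdir(parents=True, exist_ok=True)
    sm = report.score_matrix
    names = [res.algorithm for res in report.overall]

    def bar(values, title, ylabel, fname):
        fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(names)), 4))
        ax.bar(range(len(names)), values, color="steelblue")
        ax.set_xticks(range(len(names)))
        ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel(ylabel)
        ax.set_title(title)
        fig.tight_layout()
        fig.savefig(chart_dir / fname, dpi=120)
        plt.close(fig)

    row_of = {name: i for i, name in enumerate(sm.algorithms)}
    for k, j in enumerate(sm.indices):
        bar([float(sm.os[row_of[n], k]) for n in names],
            f"Index {j}: {INDEX_NAMES[j]}", "original score", f"index{j}.png")
    if report.primary_score == "crs":
        bar([res.crs for res in report.overall],
            "Comprehensive ranking score (lower is better)", "CRS", "overall.png")
    else:
        bar([res.cns for res in report.overall],
            "Comprehensive normalized score (higher is better)", "CNS", "overall.png")


def write_report(
    report: ComparisonReport,
    outdir: str | Path,
    force: bool = False,
    charts: bool = False,
) -> list[Path]:
    """Write all report files into ``outdir``; returns the paths written.

    Refuses to write into a directory that already contains report files
    unless ``force`` is set.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass force=True / --force"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = outdir / "overall_table.tsv"
    _write_overall(report, path)
    written.append(path)

    for j in report.selected_indices:
        path = outdir / f"index{j}_scores.tsv"
        _write_index_table(report, j, path)
        written.append(path)
        for name in report.algorithms:
            path = outdir / f"details_index{j}_{_safe_name(name)}.txt"
            _write_details(report.index_results[name][j], path)
            written.append(path)

    path = outdir / "run_metadata.yaml"
    _write_metadata(report, path)
    written.append(path)

    if charts:
        _write_charts(report, outdir / "charts")
    log.info("wrote %d report file(s) to %s", len(written), outdir)
    return written
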