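# tfpairbench

Benchmarking toolkit for predicted cooperative transcription-factor (TF)
pairs.

Many algorithms predict which TF pairs act cooperatively in yeast, each
emitting a list of unordered TF pairs — and each paper tends to compare
against a few rivals with one or two metrics of its own choosing.
`tfpairbench` is for researchers who develop such algorithms and want a
comprehensive, objective comparison: it scores one or more prediction lists
with **eight performance indices** against a bundle of reference datasets
and condenses the results into **two overall scores**, producing ranked
tables and per-pair detail files.

## Indices and overall scores

Four TF-based indices score the pair itself: hypergeometric overlap
significance of the two TFs' physical PPI partners (−log10 p), proximity in
the PPI network (1/d for shortest-path length d), precomputed functional
similarity of the two TFs, and list-level hypergeometric overlap
significance with a gold-standard benchmark set. Four target-gene-based
indices score the pair's *common target genes* (the intersection of the two
regulons): the pair's co-regulatory coefficient, and the expression
coherence, functional coherence and physical-PPI coherence of the common
targets.

Each index yields a non-negative original score OS_j(i) per algorithm i
(higher is better). Two summaries order the algorithms:

- **Comprehensive ranking score**: CRS(i) = Σ_j rank_j(i), where rank 1 is
  the best performer in index j (ties averaged). Lower is better.
- **Comprehensive normalized score**:
  CNS(i) = Σ_j NS_j(i), NS_j(i) = OS_j(i) / max_i′ OS_j(i′),
  so 0 ≤ NS_j(i) ≤ 1 with NS_j(i) = 1 exactly for the best performer.
  Higher is better.

A seeded synthetic generator emulates all six reference datasets (PPI
network, regulation map, functional-similarity and co-expression score
tables, co-regulatory coefficients, benchmark set) with *planted*
cooperative pairs of known identity, so the whole pipeline is testable and
demonstrable without downloading yeast datasets. Real datasets are supplied
as plain TSV files (see `docs/methods.md` for formats and conventions).

## Worked example

Generate a small synthetic bundle (20 TFs, 150 genes, 8 planted pairs) with
sample prediction lists, then compare a 40-pair "user" list against five
lists of graded quality (`q0.00` contains no planted pairs, `q1.00` all of
them):

```sh
tfpairbench synth --out demo --seed 11 --n-tfs 20 --n-genes 150 \
    --n-planted 8 --list-size 12
tfpairbench run --predictions demo/lists/sample_40.tsv --name my-algorithm \
    --compare demo/lists/q0.00.tsv --compare demo/lists/q0.25.tsv \
    --compare demo/lists/q0.50.tsv --compare demo/lists/q0.75.tsv \
    --compare demo/lists/q1.00.tsv \
    --bundle demo/bundle --out demo/report --seed 11
```

which prints

```
my-algorithm: final rank 4 of 6 (crs=35, cns=4.729)
report written to demo/report
```

The user's half-planted sample list lands mid-field: better than the
low-quality lists, worse than `q0.75`/`q1.00` — exactly what a list with
50 % true cooperative pairs should do. `demo/report/` then contains
`overall_table.tsv` (per-index OS, rank and NS plus CRS/CNS per algorithm),
one `index<k>_scores.tsv` per index, and one
`details_index<k>_<algorithm>.txt` per algorithm and index with every
pair's raw score and a diagnostic. For example, the head of
`index5_scores.tsv` (co-regulatory coefficient) shows the quality gradient
directly:

```
algorithm	os	rank	ns	n_scoreable	n_total	coverage
q1.00	0.63951	1	1	12	12	1
q0.75	0.566932	2	0.88651	12	12	1
q0.50	0.483411	3	0.755909	12	12	1
```

The same comparison is available from Python:

```python
from tfpairbench import (SynthConfig, generate_bundle,
                         generate_prediction_lists, run_comparison)

bundle, planted = generate_bundle(SynthConfig(seed=11))
lists = generate_prediction_lists(bundle, planted,
                                  [0.0, 0.5, 1.0], list_size=27, seed=11)
report = run_comparison(lists[-1], lists[:-1], bundle)
for r in report.overall:
    print(r.final_rank, r.algorithm, round(r.crs, 1), round(r.cns, 3))
```

printing, at the generator's default yeast-like scale (50 TFs, 1000 genes,
27 planted pairs):

```
1 q1.00 9.0 7.934
2 q0.50 15.0 5.962
3 q0.00 24.0 2.376
```

The fully planted list wins every index (CRS 9 with L = 8 indices means it
ranked first in all but one), and CNS decreases with the planted fraction.

`tfpairbench registry` prints the metadata of the 15 published yeast
algorithms (name, venue, list size, 13–300 pairs) commonly used as
comparison partners; their actual pair lists are user-supplied files.

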