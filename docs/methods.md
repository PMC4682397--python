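# Methods

## Problem

Algorithms that predict cooperative transcription-factor (TF) pairs in yeast
emit lists of unordered TF pairs, and each publication typically compares
against only a handful of rivals with one or two ad-hoc metrics.
`tfpairbench` evaluates any such list with eight performance indices
computed against independent reference datasets, and condenses the
eight-way comparison into two overall scores so that competing algorithms
can be ordered on one axis.

## Data model

The atomic unit is the canonical unordered TF pair: identifiers are
trimmed, uppercased (standard yeast gene symbols are uppercase) and stored
with `a < b`; self-pairs are rejected because cooperativity requires two
distinct factors. Duplicate pairs in an input list are dropped with a
warning (published lists repeat pairs in either order); no alias or
systematic-name resolution is attempted — identifiers must match the
reference bundle after canonicalization, and mismatches surface as reduced
coverage, which every report shows per algorithm and index.

A reference bundle holds six datasets, all plain TSV: an undirected
physical protein–protein interaction (PPI) edge list, a TF→target-gene
regulation map, two symmetric sparse gene-pair score tables (functional
similarity, co-expression), a TF-pair co-regulatory coefficient table, and
a benchmark set of known cooperative pairs. Score tables are sparse by
contract: an absent pair means "unavailable", never zero, and propagates as
"not scoreable" rather than dragging means toward 0. The evaluation TF
universe is the union of TFs in the regulation map, the co-regulatory
table and the benchmark.

## The eight indices

Every index yields a non-negative, higher-is-better original score OS per
algorithm; per-pair raw scores are averaged over scoreable pairs (0 if
none), and coverage n_scoreable/n_total is reported beside every score.

**TF-based.**

1. *PPI partner overlap.* For pair (A, B), the universe is all PPI nodes
   except A and B; A's partners (minus B) are marked, B's partners (minus
   A) are drawn, and the overlap |N(A) ∩ N(B)| = x is tested with the
   hypergeometric upper tail P(X ≥ x). Raw score −log10(p), p floored at
   1e−300 so scores stay finite. x = 0 covers the whole support, giving
   p = 1 and raw 0 exactly.
2. *PPI shortest path.* Unweighted BFS distance d ≥ 1; raw score 1/d. The
   reciprocal (rather than negation) keeps scores non-negative, which the
   CNS normalization requires. An alternate aggregation (`mean_path`:
   reciprocal of the mean distance) is exposed behind one switch; the
   default averages per-pair reciprocals.
3. *TF functional similarity.* Table lookup; negative scores are clipped to
   0 at scoring time (counts logged), absent pairs unscoreable.
4. *Benchmark overlap.* List-level: with U = C(|universe|, 2) possible
   pairs, K benchmark pairs, m list pairs inside the universe and x of them
   in the benchmark, OS = −log10 P(X ≥ x). Per-pair records flag benchmark
   membership. m = 0 yields OS = 0 with a warning.

**Target-gene-based**, built on each pair's common targets (intersection of
the two TFs' regulons):

5. *Co-regulatory coefficient.* Pair-level table lookup, clipped at 0.
6. *Expression coherence.* Mean pairwise co-expression score over common
   targets.
7. *Functional coherence.* Same with the functional-similarity table.
8. *PPI coherence.* Fraction of common-target gene pairs (both genes in the
   PPI network) that are edges; gene pairs outside the network leave the
   denominator.

Coherence indices need at least `min_common = 2` common targets (coherence
over fewer is undefined). When C(|T|, 2) exceeds `max_gene_pairs`
(default 1000), a uniform subsample of gene pairs is scored; the subsample
RNG is derived from the run seed and the TF names (SHA-256, 31-bit), so
results are reproducible and independent of list order.

## Overall scores

Within each index, algorithms are ranked by OS descending, rank 1 best,
exact ties averaged (this conserves total rank mass n(n+1)/2 and is stable
under relabeling). The **comprehensive ranking score** CRS(i) = Σ_j
rank_j(i), lower better. The **comprehensive normalized score**
CNS(i) = Σ_j NS_j(i) with NS_j(i) = OS_j(i)/max_i′ OS_j(i′), higher
better; 0 ≤ NS ≤ 1 and NS = 1 exactly for a column maximum. An all-zero
index column carries no information and would divide by zero; its NS values
are defined as 0, with a warning. Both scores are invariant to rescaling
any index column by a positive constant. The final ordering follows the
user's chosen primary score; ties break by the other score, then by name.

## Synthetic reference bundles

The generator emulates the six reference datasets at a yeast-like,
desk-fast scale. Defaults: 50 TFs, 1000 genes, Erdős–Rényi PPI at edge
probability 0.01 over all TF and gene nodes, regulons of 10–30 genes, and
27 planted cooperative pairs — the size of the curated yeast benchmark the
indices are normally run against; generated prediction-list sizes span the
13–300 range seen across published algorithms. Planted pairs receive, on
top of the background: a direct PPI edge plus 3 guaranteed shared partners
(indices 1–2); a forced 50 % regulon overlap (indices 6–8 gain scoreable
common targets); score boosts of +0.4 (capped at 1) on their own
similarity/co-regulation entries and on gene pairs among their common
targets (indices 3, 5, 6, 7); and edges among 30 % of their common-target
gene pairs (index 8). Baseline scores are Gaussian, mean 0.3, sd 0.15,
clipped to [0, 1]. The benchmark is the planted set (index 4).

All randomness derives from one seed through a fixed substream order
(planted pairs, regulation map, PPI, functional similarity, co-expression,
co-regulation, benchmark decoupling), so bundles are reproducible
component-wise and serialize byte-identically.

The generator verifies machinery, not biology: degree distributions,
regulon sizes and score distributions are simple bounded noise, not fits to
real yeast data. Passing tests show the indices and overall scores behave
correctly on data with known structure; they do not certify performance
numbers on real yeast datasets, where coverage, name mismatches and score
distributions are far messier.

## Validation experiments

*Planted-signal recovery.* For each replicate a default-scale bundle is
generated with a grid of prediction lists whose planted fraction q runs
over {0, 0.25, 0.5, 0.75, 1} (size 27, so the q = 1 list is exactly the
planted set); the full eight-index comparison is run and each list's CNS
recorded. Across 50 seeded replicates the q = 1 list beats the q = 0 list
in every replicate, Spearman ρ(q, CNS) is positive in every replicate, and
mean CNS is monotone in q.

*Null calibration.* Null-mode bundles switch off every planted signal and
draw the benchmark independently of the planted labels, so no list is
genuinely better. Calibration compares the nominally planted list against
four independent uniformly drawn lists of the same size: all five are then
exchangeable, and the planted list's final rank should be uniform over the
five positions. The q-graded lists of the recovery experiment are
deliberately *not* reused here: they are nested samples of one pool, so
neighbouring lists share most pairs, score near-identically, and pile up
in middle ranks for purely combinatorial reasons — a bias that would
masquerade as miscalibration of the scorer. Null calibration runs at a
reduced scale (30 TFs, 200 genes, 10 planted pairs, 200 replicates) since
the question needs many replicates, not large bundles; a chi-square
goodness-of-fit test against uniform is not rejected at α = 0.01.

## Numerical and degenerate-input conventions

- Hypergeometric p-values are clamped to (1e−300, 1]; −log10(p) is
  therefore finite and ≤ 300.
- OS = 0 whenever an algorithm has no scoreable pair under an index.
- Negative user-supplied table scores are clipped to 0 at scoring time (not
  at load), preserving the data while keeping the normalization's bounds.
- Exact duplicate rows in score tables collapse; the same pair with two
  different scores is an error, not a silent overwrite.
- Report writers iterate in sorted order with fixed `%.6g` formatting, so
  identical inputs, configuration and seed reproduce byte-identical files
  (including the subsampled indices 6–8).

## Known limitations

- No gene-name synonym resolution; users must harmonize identifiers before
  loading.
- The coherence definitions (mean pairwise score, edge fraction) are this
  package's operationalization; other benchmarking implementations may
  weight common-target structure differently, so absolute OS values are not
  comparable across implementations — rankings within one run are the
  supported output.
- Index 4's evaluation universe defaults to the bundle's TF universe and is
  a genuine modelling choice; a different universe changes the absolute
  significance (not the ordering of nested lists).
- Statistical uncertainty on ranks (e.g. bootstrap over pairs) is not
  computed.
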