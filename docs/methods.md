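# Methods

## Problem and scope

`ccshift` quantifies directional change in cell–cell communication (CCC)
inferred from transcriptomics between two biological states — consecutive
ages, disease vs. healthy, treated vs. untreated. Its input is the
*downstream* table contract of LIANA-style consensus inference: per state,
one row per (source cell type, target cell type, ligand, receptor) with a
mean-expression magnitude `lr_mean` and two per-method p-values
(CellPhoneDB-style and CellChat-style). Nothing upstream — raw counts, QC,
normalisation, clustering, annotation, the inference run itself, ortholog
mapping, GO enrichment — is in scope.

## Model

An interaction is called *present* in a state when both method p-values are
strictly below the threshold (default 0.05); the filter is applied to each
state table independently, since each state's inference run is independent.
Presence is a statistical call: absence is never statistically confirmed,
which is why losses are only ever "potential".

For each directed communication type t(A→B) (A may equal B: autocrine
signalling is allowed) the present ligand–receptor (LR) pairs of reference
state 1 and comparator state 2 form sets L1 and L2 with intersection
I = L1 ∩ L2 and intersection ratios r1 = |I|/|L1|, r2 = |I|/|L2|.

**Shrink/Expand (SE) score.** A bounded directional set-similarity score.
Under the default `semantic` convention

    SE = |I| · (1/|L1| − 1/|L2|) = r1 − r2 ∈ [−1, 1]

so a comparator that strictly gains pairs scores positive (expansion), one
that strictly loses pairs scores negative (shrinkage), and equal-size sets
score exactly zero. The `literal` convention returns r2 − r1, the same
magnitude with the opposite sign; it exists because the two orderings of
the ratio difference circulate and only one of them makes "expansion"
positive — the package treats the semantic reading as normative and keeps
the other for audit. SE = 0 does **not** imply an unchanged network:
disjoint equal-size sets (complete turnover) also score 0, which is why SE
is always reported alongside the gain/loss ratios below.

**Unit classification.** Each (communication type, LR pair) combination —
a *communication inference unit* — is classified per transition as
Consensus C = I, Gain G = L2 \ L1, or Potential Loss PL = L1 \ L2. These
partition L1 ∪ L2; |C| + |G| = |L2| and |C| + |PL| = |L1|. The turnover
fractions are GR = |G|/|L2| and PLR = |PL|/|L1|; GR = 1 means the
comparator's communication content is completely new, PLR = 0 means every
reference interaction is preserved.

**Degenerate sets.** The formulas are undefined when a type exists in only
one state. Such types are reported with the limit values (direction
`emergent`, SE = +1, when the reference set is empty; `vanished`, SE = −1,
when the comparator set is empty) and flagged so users can exclude them
(`aggregate_organ(include_single_state=False)`). A type empty in both
states is an error, and such types never arise from `compare_states`,
which only visits types present in at least one state. GR is reported as
missing (NaN) for an empty comparator and PLR for an empty reference.

**Organ aggregation.** Types are counted as expanding (SE > 0) or
shrinking (SE < 0); stable types are excluded from the total.
SE_organ = (N_expand − N_shrink)/(N_expand + N_shrink) ∈ [−1, 1]. When no
type changes direction the organ score is reported as undefined (with a
warning), not as 0 — an all-stable organ and a perfectly balanced organ
are different findings.

## Statistics

**Consensus-shift test.** Within one communication type, the paired
`lr_mean` values of the consensus pairs are compared across states with
the two-sided Wilcoxon signed-rank test (differences comparator −
reference). Zero differences are dropped before ranking (classic Wilcoxon
handling rather than Pratt's; logged, since the choice is conventional).
The exact null distribution is used for n ≤ 25 without tied magnitudes,
otherwise a normal approximation with continuity correction; both are
delegated to `scipy.stats.wilcoxon` and checked in the test suite against
full sign-assignment enumeration. A type with no non-zero difference is
flagged untestable rather than given a p-value. Significance is called at
0.05 per type without multiple-testing correction by default, mirroring
conventional practice for this analysis; a Benjamini–Hochberg option
(`bh_correction`) re-makes the calls across types.

**Permutation null for non-stochastic categorical change.** If state
transitions affected communication randomly, the three category labels
would scatter across an LR pair's occurrences; if change is ordered, most
pairs carry a single label. The observed statistic is the number of
top-k (default 20) highest-frequency pairs carrying ≥ 2 distinct category
labels within a stage (`multi_label_pairs`; the alternative
`multi_label_occurrences` counts every extra label). Each of the
n_permutations (default 200) replicates draws k distinct pairs uniformly
without replacement from the stage's pair universe, assigns each of a
pair's communication-type occurrences (its summed frequency) an
independent uniform category, and recomputes the statistic. The p-value is
the add-one lower-tail estimate (1 + #{null ≤ observed})/(n + 1) — never
exactly zero, with resolution floor 1/(n+1) ≈ 0.005 at the default 200
replicates — and the report includes the full null distribution and its
5th percentile. All draws come from one seeded `numpy` generator consumed
in a fixed order, so reports are bit-reproducible and invariant to
universe row order.

## Shortlisting and molecule analysis

**Two-cluster partition.** Gain and potential-loss units are shortlisted
by magnitude: the `lr_mean` values of one category (per communication type
by default; `pooled_shortlist` pools across types) are split into two
groups minimising the within-group sum of squares — exact one-dimensional
two-means, computed by scanning every split point of the sorted values
(the optimal 1-D two-group partition is always contiguous in sorted
order). The higher-mean group is selected. Objective ties resolve to the
smaller high group; with fewer than two distinct values no split exists
and everything is selected with a degenerate flag. Gains are scored with
the comparator state's `lr_mean` (where they exist), losses with the
reference's.

**Consensus rank changes.** Consensus units are shortlisted by dynamics
instead: within each communication type, pairs are ranked by `lr_mean`
separately in each state (rank 1 = largest; ties get average ranks), and
the absolute rank change is clustered as above, high-score cluster
selected.

**Frequency ranking.** Per stage interval and category, a pair's frequency
is the number of distinct communication types in which it shows that
change (a pair gained in two types has gain-frequency 2). The top-k cut is
deterministic: sort by (frequency desc, category asc, ligand asc, receptor
asc). For the permutation test, pairs are ranked by total frequency across
categories and all category labels of the selected pairs are retained.

**Molecule decomposition.** Top pairs are decomposed into individual
molecules; multi-subunit complex names are split on `_` (the LIANA
convention; configurable). Occurrence counts accumulate per (molecule,
interval, category) with a ligand/receptor role breakdown; without
complexes the counts sum to exactly twice the number of pairs.

## Synthetic data

The generator plants structure first — per communication type, explicit
C*/G*/PL* sets between consecutive states — and derives tables from it, so
the pipeline's output can be compared with exact expectations. Defaults
emulate a Tabula-Muris-Senis-like organ: 7 cell types (49 directed
communication types), 5–20 consensus and 0–8 gained/lost pairs per type
per transition, log-normal `lr_mean` (location 0, scale 1: positive,
right-skewed, median 1 — the shape of expression-mean magnitudes),
synthetic token vocabularies (CT01…, LIG001–REC001) with explicit
`planted_sets` accepting real gene symbols. Significant rows draw both
p-values uniformly from (0, threshold/2]; decoy rows fail the filter on at
least one method with that p-value in [threshold, 1], so the strict
boundary at the threshold is never hit by chance and is tested explicitly
instead. The lifespan series applies per-transition (gain, loss) drift to
every type; the default profile ((6,1), (4,2), (2,4), (1,5)) over the five
default ages (1, 3, 18, 21, 30 months) expands early and shrinks late, the
organ-level trajectory shape the framework is designed to resolve.

What the generator does **not** emulate: correlated expression between
pairs, cell-type abundance effects on inference power, method-specific
p-value dependence, or batch structure. Passing tests therefore establish
the correctness of the set arithmetic, statistics and bookkeeping on the
table contract — not robustness of upstream inference on real data.

## Numerical and design choices

- Strict `<` at the p-value threshold (boundary rows dropped).
- Duplicate interaction keys within one state collapse deterministically
  (min first p-value, then min second, then first occurrence), logged.
- Text joins are case-sensitive exact matches; no gene-symbol
  normalisation.
- Communication types are directed to match the input contract; a
  `symmetrize_comm_types` switch merges (A, B) with (B, A).
- SE equality with zero is exact in floating point: |I|·(1/|L1| − 1/|L2|)
  is computed from integers and is exactly 0.0 when |L1| = |L2| or I = ∅.
- One global seed per run; the CLI records it in the manifest along with
  input digests, so identical manifests imply byte-identical outputs.

## Problem sizes

Tests and the acceptance checks run at desk scale by design: exhaustive
set enumeration on a 5-element universe (961 ordered subset pairs),
1,000-pair random-set oracle comparisons, 100-seed round-trip recovery at
8 communication types per seed, 500-vector clustering oracle checks at
n ≤ 12, full sign enumeration at n ≤ 8, and 50 calibration replicates of a
200-permutation null at k = 20 over a 60-pair universe. These sizes
exercise every code path and invariant; organ-scale runs (49 types,
hundreds of pairs) are covered by the generator defaults in the round-trip
and CLI tests.

## Known limitations

- SE weights every pair equally; expression-magnitude weighting is
  deliberately not implemented.
- Gains and potential losses are statements about statistical calls, not
  biology: power, sampling depth and thresholding all masquerade as
  change. The framework's own caveat — SE = 0 under complete turnover —
  is surfaced in the outputs (GR = PLR = 1 with direction `stable`).
- The consensus-shift tests pool all consensus pairs of a type per
  interval; no within-type dependence structure is modelled.
- Whether single-state (emergent/vanished) types belong in the organ
  aggregate is context-dependent; both behaviours are provided and the
  default includes them.
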