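# Methods

## Model

`etbiclust` mines *constant-row biclusters* from a real-valued gene ×
condition expression matrix, viewed through association mining: genes are
items, experimental conditions are transactions. A transaction *t* supports
a gene set *G* when the expression values of the genes in *G* at *t* are
coherent; a bicluster is a gene set together with its supporting
transactions.

Coherence of one transaction is the **range** test: after restricting to a
strictly same-sign retained set, the relative range of absolute values
`(max|v| − min|v|) / min|v|` must not exceed a threshold α. Sign
enforcement means a supporting condition has all its retained genes either
up- or down-regulated together (the same genes may flip direction in a
different condition). Pattern strength is the **RangeSupport**
`RS(B) = Σ_t min_{g ∈ retained(t)} |v_{g,t}|` — the binary-support analogue
for real values, where each supporting transaction contributes the minimum
absolute retained value.

**Error tolerance.** Real compendia fragment true biclusters with noise. A
transaction may therefore discard up to `⌊k·ε⌋` of its *k* values as errors
(ε ∈ [0, 1); ε = 0 is the exact mode, equivalent to range-support pattern
mining without tolerance). Errors are restricted to the extremes of the
sorted value list: for a budget *e*, every split "discard the *i* smallest
and *j* largest, i + j ≤ e" is enumerated, mirroring the 1-error (min or
max) and 2-error (two minima / one of each / two maxima) case analyses and
their generalisation. Interior values are never discardable; this keeps
the per-transaction check O(e²) and matches the intended procedure. A
discarded value may have any sign; a zero can never be retained (its sign
and relative range are undefined) but is discardable within the budget.
Among passing splits at the smallest feasible *e*, the one maximizing the
contribution is taken (ties: fewer discards from the maximum end) — a
deterministic choice favouring the strongest support.

The definitional constraints on an emitted bicluster *B* = (G, T) are
`RS(B) ≥ RS_threshold` and, for every t ∈ T, `E(values(t, G)) ≤ ε·|G|`
where `E` is the minimum number of extreme discards that makes the rest
coherent. With the floored per-level budget the second constraint holds a
fortiori.

## Mining algorithm

Level-wise, bottom-up:

1. **Singletons**: gene *g* is valid iff `Σ_t |v_{g,t}| ≥ RS_threshold`
   (zero cells contribute nothing and are not supporting).
2. **Candidate generation**: two valid k-patterns sharing a (k−1)-gene
   prefix under the matrix row order are joined; a candidate survives only
   if all of its k-subsets are valid (Apriori pruning).
3. **Budgets and candidate transactions**: the budget at level k is
   `⌊k·ε⌋` (computed as `floor(k·ε + 1e−9)` to absorb binary float
   representation of ε). If the budget grew from level k (an *error
   step*), candidate transactions are the union of the subsets' supports;
   otherwise (*non-error step*) their intersection. Every candidate
   transaction is re-checked from scratch with the new budget — retained /
   discarded partitions can shift when a gene is added even if the budget
   does not.
4. **Validation**: supporting transactions are those that pass;
   RangeSupport is the sum of their contributions; candidates reaching the
   threshold are kept. All levels are emitted (no closed/maximal
   filtering); redundancy is handled by selection.

For ε = 0 both range and RangeSupport are anti-monotone, so pruning is
lossless and the miner is exhaustive (verified in the tests against a
brute-force enumeration of all gene subsets). For ε > 0 range loses
anti-monotonicity; the level-wise procedure is then a heuristic that
subsumes the exact output (also asserted in tests) but cannot claim
completeness — notably RangeSupport may *grow* with the gene set across an
error step, because the union re-admits transactions that no exact subset
supported.

Two runs at different (ε, RS) settings can be merged: the union keyed by
gene set, keeping the variant with more supporting transactions (tie:
larger RangeSupport). This supports the practical recipe of an exact pass
at a lower RS band plus a tolerant pass at a higher one when a single
tolerant run is too expensive.

The miner is exposed as a scikit-learn-style estimator
(`ETBiclusterMiner(alpha, epsilon, rs_threshold).fit(X)`) with
`biclusters_`, boolean `rows_`/`columns_` membership arrays, and
`get_params`/`set_params`; `mine()` is the equivalent function.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| α (`alpha`) | relative-range coherence threshold, dimensionless | 0.5 | 0 demands exactly equal values; 0.3–0.8 are typical for log-ratio data |
| ε (`epsilon`) | max error fraction per supporting transaction | 0.25 | ⌊k·ε⌋ errors at level k; 0 = exact mode. Accepted on [0, 1): ε = 1 would let a transaction consist entirely of errors |
| RS (`rs_threshold`) | minimum RangeSupport | 5.0 | on the scale of the data; roughly (number of supporting conditions demanded) × (typical absolute signal) |
| `max_selected`, `max_overlap` | selection cap and pairwise gene-overlap bound | 500, 0.25 | overlap metric `|G_i ∩ G_j| / min(|G_i|,|G_j|)` — the strictest common choice, so a large pattern cannot absorb a smaller near-subset |

Threshold comparisons carry a 1e−9 absolute slack so that printed decimal
parameters behave as written under binary floating point.

## Selection and scoring

Top-bicluster selection sorts by gene count (descending), breaking ties by
the Cheng–Church mean squared residue
`H = mean (a_ij − a_iJ − a_Ij + a_IJ)²` computed **on retained cells
only** (error cells are excluded from the means and the sum; a single-cell
block scores 0), then by lexicographic gene set for determinism. Greedy
acceptance enforces the overlap bound against all previously selected
patterns. Size is |genes| only, not |genes| × |conditions|: tolerant
patterns carry large condition sets, which would otherwise let highly
overlapping gene sets through. Singletons are excluded by default.

## Evaluation stack

* **Enrichment**: upper-tail hypergeometric p-value `P(X ≥ k)` per
  (bicluster, term) pair over a configurable universe (default: union of
  the collection's sets, i.e. the annotated genes; bicluster genes are
  intersected with the universe first, and an empty intersection scores
  p = 1). No multiple-testing correction — the p-values compare
  collections rather than call individual hits. Per-bicluster enrichment
  score: `−log10(p_min)`.
* **Biomarkers**: a condition supports a biomarker when it is a
  supporting transaction. On the 2×2 case/control × supports/doesn't
  table, the odds ratio is `(a·d)/(b·c)` with the Haldane–Anscombe +0.5
  on all cells when any cell is zero, and the p-value is a two-sided
  Fisher exact test (the standard companion of the odds ratio on a 2×2
  table; the specific exact test is otherwise a free choice). Retained:
  p < 0.05 and OR outside [0.5, 2.0].
* **Random gene sets**: per bicluster of gene size s, `reps` uniform
  s-subsets of the universe (without replacement within a draw; sets may
  repeat across draws); empirical p = fraction of random sets whose score
  *strictly* exceeds the actual one, so ties favour the actual pattern.
  Zero exceedances are reported as "< 1/reps" rather than mapped to an
  arbitrary small number. A per-threshold summary counts how many of the
  random collections beat the actual collection's enriched fraction.
* **Data shuffling**: each gene's row is permuted independently,
  preserving every per-gene value distribution exactly while destroying
  inter-gene correlation; re-mining the shuffled matrix estimates the
  background pattern yield.

All randomized operations take an explicit seed and are bit-for-bit
reproducible.

## Synthetic data

`generate(PlantSpec)` embeds constant-row blocks (per-gene positive base
magnitudes, a ±/mixed sign per condition, multiplicative jitter bounded so
clean transactions stay within the target α) in an i.i.d. background,
uniform on [−2, 2] by default — the value range of log-ratio compendium
data. A fraction `error_rate` of planted cells is replaced by background
draws, with three deliberate properties:

* at most `⌊ε·gene_count⌋` corruptions per planted condition, so the
  planted support stays recoverable at the target tolerance;
* at most `⌈error_rate·condition_count⌉` corruptions per gene, emulating
  spatially uniform noise (no single gene soaks up all the corruption);
* the replacement draw is redrawn until it actually breaks the column's
  coherence at the target α — a "corruption" landing inside the coherent
  range would not be an error, and the ground truth must describe real
  corruption.

What the generator does **not** emulate: correlated noise, batch effects,
heavy-tailed expression distributions, overlapping modules sharing genes,
and missing values. Passing recovery tests therefore demonstrate the
mechanism (fragmented patterns are stitched back together by the error
budget) rather than performance on any real compendium.

The package also ships a reconstructed 5 × 8 walk-through matrix
(`worked_example_fixture`). Its constrained cells satisfy, simultaneously,
every printed intermediate of the reference walk-through (pair *ab*:
support {t1,t2,t3,t4,t7,t8}, contributions 2 + 2.1 + 4 + 6.5 + 3 + 2 =
19.6; triple *abc*: support {t2,t4,t8}, RS 10.6; quadruples *abcd*/*abce*
and quintuple *abcde*: support {t1,...,t6,t8}, RS 33.6; error values 8 in
t1, 9 in t3, 20 in t5; t7 failing the quadruple even after one discard;
the quintuple absent at ε = 0). The free cells are one canonical choice
among many; consistency forces some additional valid triples and
quadruples beyond the ones the walk-through names (e.g. *acd*, *bcd*) —
indeed those are exactly what make the quadruple-level union of subset
supports reach {t1,...,t6,t8}.

## Study conditions used by tests and the acceptance script

Chosen once, at desk scale: recovery experiments plant a 5-gene ×
10-condition block (base magnitude 1.8, jitter 0.05, 10% corruption) in a
20 × 30 matrix and mine at α = 0.5, RS = 11.5 — about seven conditions'
worth of minimum planted contribution, above what the exact mode can
accumulate for the full set once 5 of 10 columns are corrupted (≤ ~9.5)
and below the weakest pattern on the tolerant miner's path to it
(≥ ~12.0). Exact-mode completeness is checked against brute-force
enumeration on 50 random matrices up to 8 × 10; the shuffle test uses 20
fixed shuffle seeds; randomization uses 1000 replicates where the
empirical p-value granularity matters and fewer in smoke tests.

## Known limitations

* For ε > 0 the search is heuristic: patterns whose subsets fall below
  the RS threshold are unreachable even if they satisfy the definition.
* Error budgets are row-wise only; a gene inside a wide bicluster may in
  principle contribute error values in every supporting transaction
  (a column-wise budget is a known extension, not implemented).
* The per-transaction check enumerates extreme-discard splits only; an
  adversarial interior outlier is never discardable (by design).
* Runtime grows with the candidate lattice; the optional
  `max_candidates_per_level` guardrail truncates (with a warning) rather
  than sampling, trading completeness for bounded memory.
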