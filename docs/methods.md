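# Methods

This note documents the models implemented in `idpmeta`, the choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not establish.

## Problem and labels

Per-residue two-state prediction of intrinsic disorder. Reference labels
are two-state (ordered / disordered) with an explicit third *unknown*
state; every metric and every training routine skips unknown residues.
The operational definition of disorder follows crystallographic
practice: residues present in a chain's SEQRES but absent from the
model (REMARK 465 in PDB-format files) are disordered, everything else
ordered. Coordinates are 1-based closed intervals throughout. Sequences
longer than 1000 residues trigger a warning but are processed — the
limit is a policy inherited from upstream predictors, not a property of
the math.

With SEQRES-only toy input there is no coordinate record from which to
recover author residue numbering, so REMARK 465 extraction assumes
sequential numbering 1..L by default and accepts an explicit
`numbering` map of (residue number, insertion code) keys when the
caller has one. NMR-ensemble-derived labels are consumed as pre-made
two-state annotations only; no ensemble variability criterion is
implemented.

## Evaluation metrics

* **S_w** uses the class-weighted numerator
  `w_dis·TP − w_ord·FP + w_ord·TN − w_dis·FN` normalized by
  `S_max = w_dis·(TP+FN) + w_ord·(TN+FP)`, the score of a perfect
  predictor. This normalization satisfies the defining properties of
  the score (1 for a perfect predictor, 0 in expectation for any
  label-independent one). A legacy variant normalizing by
  `w_dis·(TN+FN) + w_ord·(TN+FP)` — which cannot reach 1 on imbalanced
  data — is available behind `printed_denominator=True` for
  compatibility with older write-ups.
* **Decision convention:** a residue is called disordered iff
  score ≥ threshold. With `≥`, threshold 0 produces the all-disordered
  degenerate call that anchors the (1, 1) ROC endpoint; a `strict` flag
  flips to `>`.
* **S_ww** averages S_w over the inclusive grid 0.00–1.00 in steps of
  0.01 (101 points). The grid is also used for threshold selection,
  with ties broken toward the lowest threshold (so constant scores
  select 0.0).
* **ROC/AUC** by trapezoidal integration over all distinct score
  thresholds (delegated to scikit-learn's `roc_curve`); it equals the
  tie-aware pairwise concordance probability, which the tests verify
  exactly against a brute-force pair count.
* **MCC** with the standard 0-on-zero-marginal convention.
* **Bootstrap error bars** subsample ⌈0.8·n⌉ of the *targets* without
  replacement, 1000 times, and report the mean absolute deviation of
  the recomputed pooled metric from the full-data value. Subsampling
  (not resampling with replacement) matches the "80% of the targets
  randomly selected" design. Draws on which the metric is undefined
  (e.g. single-class) are redrawn, with a retry cap. No separate
  standard-error estimator is provided.
* **Class weights** are computed from the pooled reference being scored
  (per dataset, not per target), matching pooled-residue evaluation.
* **Wilcoxon signed-rank** (two-sided) for paired per-target score
  comparisons: exact null for ≤ 25 non-zero differences, tie-corrected
  normal approximation above; all-zero differences return p = 1.
* **Cross-validation** assigns residues to 10 bins of nearly equal size
  (differing by at most 1), at residue level by default as the
  calibration protocol prescribes; for leakage-safe experiments split
  whole targets instead.

## Consensus predictor

Binary calls are encoded disordered = 1, ordered = 0.01; the small
positive value (rather than 0) guards against zero denominators when a
residue's every prediction is "ordered". In continuous mode, methods
that provide `[0, 1]` scores contribute them directly; in binary mode
continuous columns are first binarized at the method's native call
threshold (default 0.5).

Method weights are each method's best-threshold S_w on the calibration
set — the score is output-type-agnostic, so binary and continuous
methods are weighted on the same scale. Negative S_w is floored at 0
(a negative weight would invert a predictor). Missing per-residue
predictions are dropped from both numerator and denominator
(per-residue re-normalization) rather than imputed; a residue missing
every method propagates as missing and is excluded from metrics.

The terminal correction multiplies the score of residues at offsets
1–15 from either terminus by
`P(disordered | offset) / P(disordered | interior)`, estimated from the
calibration labels and serialized with the model. The raw ratio is kept
even when < 1. Chains of ≤ 30 residues have no unambiguous interior and
are skipped during estimation; at prediction time, where the two
15-residue windows overlap, the nearer terminus wins and ties go to the
N-terminal factor. Corrected scores are clipped to `[0, 1]`.

The repair filter is a run-based rule: every maximal run of predicted
disorder of length ≤ 3 flanked by predicted order on *both* sides is
converted to order; runs touching a terminus are kept. This run rule
(rather than a sliding-window majority vote) is the form that exactly
reproduces the canonical worked example `DDD---D--` → `DDD------`
(terminal `DDD` kept, interior singleton removed). It is idempotent and
one-sided (never converts order to disorder).

## Coverage predictor

Each fold-recognition hit is classified good/medium/poor from its raw
score via fixed per-program cutoffs (e-value-like programs compare with
`<`, score-like with `>`; boundary values classify to the worse tier).
PSI-BLAST and HHsearch each run in two modes sharing one cutoff row,
giving 8 method modes × 3 tiers = 24 weight cells. Up to 10 hits per
method mode are retained, by rank.

The per-residue formula — order evidence
`evidence(r) = Σ_hits w[mode, tier] · 1[r covered]`, disorder score
`1 − evidence(r) / Σ_hits w[mode, tier]` — is this package's central
reconstruction: the residue-level combination rule is not fully pinned
down by the qualitative description the method derives from, so it is
kept behind one function (`predict_gs3d`) where alternatives (max or
rank-decayed accumulation across a method's alignments) could be
swapped. Summation preserves monotonicity (an added hit never increases
a covered residue's disorder score) and makes predictions invariant to
scaling all 24 weights. A target with no hits at all scores fully
disordered — defensible (no detectable structured counterpart) but
aggressive; the floor is configurable (`no_hit_score`, default 1.0).

## Genetic algorithm

Real-valued genomes bounded to `[0, 1]`, tournament selection (size 3),
uniform crossover (probability 0.9), per-gene Gaussian mutation
(probability 0.02, σ = 0.1), elitism 1, population 80, 100 generations.
These hyperparameters are package defaults exposed in `GAConfig`; the
best-fitness trace is non-decreasing by elitism and runs are
deterministic given a seed. Fitness is the pooled best-threshold S_w of
the genome's predictions (or pooled S_ww for the threshold-free
variant). For speed, per-target coverage counts are precomputed as a
24 × N matrix so each fitness evaluation is a matrix product plus a
vectorized threshold sweep.

The combined model appends the two channel weights (a, b) to the tier
genome — 26 genes trained jointly; the channel mix is the linear convex
combination `(a·c + b·t)/(a + b)`. Genomes with `a + b ≈ 0` receive the
worst fitness rather than raising. An alternative reading of "adding a
second dimension" as a 24 × 2 interaction matrix was considered and
rejected as the less parsimonious interpretation. Thresholding and
repair are applied after combination, reusing the consensus machinery.

## Synthetic benchmark

The generator plants disorder in geometric segments (mean length 12
residues) rather than i.i.d. per-residue noise, because the repair
filter and terminal correction are only exercised by runs. Defaults
emulate the composition of the combined calibration data: 23.45%
disordered residues, chains of 50–300 residues, and a two-fold disorder
enrichment within 15 residues of each terminus (the segment-process base
rate is compensated so the overall fraction still matches the target).
Thirteen simulated predictors draw scores from per-class Beta
distributions — chosen for `[0, 1]` support and a single separation
knob — spanning AUCs of roughly 0.71–0.86, the range published primary
methods occupy; four of them are binary-only. Simulated hits are
*informative* (covering ordered segments, leaking into disordered ones
at rate 0.05) with probability equal to the generative weight of their
(mode, tier) cell, and draw raw scores inside disjoint per-tier bands,
so tier classification recovers the emitted tier exactly.

What passing tests on these fixtures establish: the arithmetic of every
metric (against brute-force oracles), the end-to-end behavior of all
three predictors, GA weight recovery, and the qualitative
consensus-beats-constituents property under heterogeneous independent
errors. What they do not establish: performance on real proteins —
real primary predictors have *correlated* errors (shared training data
and features), real disorder has length and compositional structure the
generator ignores, and real fold-recognition coverage is far noisier
than the simulated hit model. Absolute AUC values on fixtures are
therefore not comparable to published benchmark numbers.

## Problem sizes and numerical notes

Tests run the GA at reduced budgets (population 16–50, 5–50
generations) except the weight-recovery check, which uses the full
default configuration on 50 targets (~9,000 residues; a few seconds on
one CPU thanks to the precomputed coverage matrices). Stochastic
assertions use fixed seeds and the tolerances stated inline. The
threshold grid is generated once (`np.linspace`, rounded to 2 decimals)
and shared between S_ww, threshold selection and the grid tests, so
grid-point identity is exact. Scores read from TSV may exceed `[0, 1]`
by at most 1e-6 (clipped with a warning); larger excursions are errors.
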