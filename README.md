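# idpmeta

Meta-prediction of intrinsically disordered protein regions, with
CASP-style evaluation machinery and a synthetic benchmark generator.

Intrinsically unstructured proteins (IUPs) and regions (IURs) lack a
stable three-dimensional structure; predicting which residues of a
sequence are disordered is a standard per-residue two-state problem.
Dozens of primary predictors exist, each with its own biases. This
package implements, as scikit-learn-style estimators, three ways to do
better than any single method:

* **`ConsensusDisorderPredictor`** — an accuracy-weighted consensus of
  per-residue scores from an arbitrary panel of primary predictors. A
  binary mode encodes two-state calls as disordered = 1, ordered = 0.01;
  a continuous mode uses raw `[0, 1]` scores where available. Each
  method's weight is its own S_w on a calibration set.
* **`TemplateCoveragePredictor`** — disorder inferred from *gaps in
  fold-recognition coverage*: regions that no alignment to a known
  structure covers have no detectable structured counterpart. Eight
  method modes contribute ranked alignments, each classified
  good/medium/poor from its native score; the 24 per-(mode, tier)
  weights are trained with a genetic algorithm.
* **`CombinedDisorderPredictor`** — a convex combination of the two
  channels, with the two mixing weights trained jointly with the 24 tier
  weights as one 26-gene GA genome (fitness: pooled S_w, or S_ww for
  the threshold-free variant).

## The statistics at the core

Writing TP/TN/FP/FN for the confusion counts with *disordered* as the
positive class, and `w_dis` / `w_ord` for the ordered / disordered
fractions of the reference:

```
S_w  = ( w_dis·TP − w_ord·FP + w_ord·TN − w_dis·FN ) / ( w_dis·(TP+FN) + w_ord·(TN+FP) )
```

S_w rewards a correct call of the rarer disordered class more than a
correct ordered call; 1 is perfect, 0 is the expectation of any
label-independent predictor. **S_ww** is the mean of S_w over decision
thresholds 0.00, 0.01, …, 1.00. The package also provides MCC, ROC/AUC,
target-subsampling bootstrap error bars (80% of targets, 1000 draws,
mean absolute error), the paired Wilcoxon signed-rank comparison, and a
residue-level 10-fold cross-validation splitter.

The consensus score of residue *r* is `Σ_m w_m·s_m(r) / Σ_m w_m`; a
terminal correction then multiplies scores within 15 residues of either
chain end (termini are on average more disordered), the decision
threshold is the S_w-optimal point on the 0.01 grid, and a repair filter
deletes isolated short (≤ 3 residue) disorder calls flanked by order,
e.g. `DDD---D--` → `DDD------`.

The coverage score of residue *r* is `1 − evidence(r) / Σ_hits w(hit)`,
where each retained hit (up to 10 per method mode, by rank) adds its
tier weight to the residues its alignment covers. A target with no hits
at all scores fully disordered.

## Worked example

Everything below runs on synthetic fixtures from `idpmeta.simulate` —
sequences with planted disorder segments, thirteen simulated predictors
of heterogeneous accuracy, and fold-recognition hits that avoid
disordered regions:

```python
import numpy as np
from idpmeta import (
    ConsensusDisorderPredictor, TemplateCoveragePredictor,
    CombinedDisorderPredictor, roc_auc,
)
from idpmeta.simulate import (
    SimConfig, gen_labels, sim_profiles, sim_hits, default_true_tier_weights,
)

cfg = SimConfig(n_targets=40, seed=7)
labels = [lab for _, lab in gen_labels(cfg, seed=7)]
profiles = sim_profiles(labels, cfg, seed=8)
hits = sim_hits(labels, default_true_tier_weights(), cfg, seed=9)
states = np.concatenate([lab.states for lab in labels])

cons = ConsensusDisorderPredictor().fit(profiles, labels)
cons_scores = cons.predict_scores(profiles)
print("consensus threshold:", cons.threshold_)
print("consensus AUC:", round(roc_auc(np.concatenate(cons_scores), states)[1], 3))

tmpl = TemplateCoveragePredictor(random_state=0).fit(hits, labels)
md = CombinedDisorderPredictor(random_state=0).fit(list(zip(cons_scores, hits)), labels)
```

Output:

```
consensus threshold: 0.53
consensus AUC:       0.934
coverage AUC:        1.0
combined AUC:        1.0
component weights a, b: (0.22, 1.0)
first target calls:  ---------------------------DDDDDDDDDDD-- ...
```

The consensus (AUC 0.934) clearly beats its best constituent (≈ 0.86 by
construction); on this fixture the coverage channel is highly separable,
so the combined model leans on it (b ≫ a) and the final call strings
mark the planted disordered segments.

A command-line interface mirrors the library:
`idpmeta simulate | train | train-3d | predict-consensus | predict-3d |
predict-md | evaluate`, reading/writing FASTA, label and hit TSVs,
per-residue DR-style prediction dumps, and a human-readable trained-model
artifact. Exit codes: 0 success, 2 invalid input, 1 internal error.

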