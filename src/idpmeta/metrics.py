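"""Evaluation statistics for two-state disorder prediction.

Implements the CASP-style assessment toolkit: the class-weighted score S_w,
its threshold-averaged variant S_ww, the Matthews correlation coefficient,
ROC/AUC, bootstrap mean-absolute-error bars, a paired Wilcoxon comparison
and a residue-level k-fold splitter.

Decision convention: a residue is called disordered iff its score is
**greater than or equal to** the threshold (``strict=True`` flips to a
strict comparison). With ``>=``, threshold 0 yields the all-disordered
degenerate call needed for the (1, 1) ROC endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .types import (
    DISORDERED,
    ORDERED,
    UNKNOWN,
    ClassWeights,
    ConfusionCounts,
    DisorderLabels,
    InputError,
)

__all__ = [
    "RocCurve",
    "confusion_at",
    "sw",
    "mcc",
    "roc_auc",
    "sw_grid",
    "sww",
    "bootstrap_mae",
    "wilcoxon_paired",
    "kfold_residue_bins",
    "write_evaluation_report",
]

#: the S_ww / threshold-selection grid: 0.00, 0.01, ..., 1.00 (101 points,
#: inclusive endpoints).
THRESHOLD_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class RocCurve:
    """ROC curve sampled at descending score thresholds."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


def _states_of(labels: DisorderLabels | np.ndarray) -> np.ndarray:
    if isinstance(labels, DisorderLabels):
        return labels.states
    return np.asarray(labels, dtype=np.int8)


def _known_pairs(
    scores: np.ndarray, labels: DisorderLabels | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop unknown-state residues and missing scores; validate lengths."""
    scores = np.asarray(scores, dtype=float)
    states = _states_of(labels)
    if scores.shape != states.shape:
        raise InputError(
            f"scores ({scores.shape}) and labels ({states.shape}) differ in length"
        )
    if scores.size == 0:
        raise InputError("empty input")
    keep = (states != UNKNOWN) & ~np.isnan(scores)
    if not keep.any():
        raise InputError("no scored residues with known labels")
    return scores[keep], states[keep]


def confusion_at(
    scores: np.ndarray,
    labels: DisorderLabels | np.ndarray,
    threshold: float,
    strict: bool = False,
) -> ConfusionCounts:
    """Confusion counts at one decision threshold (disordered = positive)."""
    s, y = _known_pairs(scores, labels)
    pred_dis = (s > threshold) if strict else (s >= threshold)
    dis = y == DISORDERED
    return ConfusionCounts(
        tp=int(np.sum(pred_dis & dis)),
        tn=int(np.sum(~pred_dis & ~dis)),
        fp=int(np.sum(pred_dis & ~dis)),
        fn=int(np.sum(~pred_dis & dis)),
    )


def sw(
    counts: ConfusionCounts,
    weights: ClassWeights,
    printed_denominator: bool = False,
) -> float:
    """Class-weighted score S_w = S / S_max, in [-1, 1].

    S = w_dis*TP - w_ord*FP + w_ord*TN - w_dis*FN with w_dis the ordered
    fraction of the reference, so a correct call of the rarer disordered
    class is rewarded more. The normalizer S_max = w_dis*(TP+FN) +
    w_ord*(TN+FP) is the score of a perfect predictor, making S_w = 1 the
    attainable maximum and 0 the expectation of any label-independent
    predictor. ``printed_denominator`` selects a legacy normalization
    (w_dis*(TN+FN) + w_ord*(TN+FP)) kept for compatibility only; it does
    not reach 1 for perfect predictions on imbalanced data.
    """
    if counts.total == 0:
        raise InputError("empty confusion counts")
    wd, wo = weights.w_disorder, weights.w_order
    s = wd * counts.tp - wo * counts.fp + wo * counts.tn - wd * counts.fn
    if printed_denominator:
        smax = wd * (counts.tn + counts.fn) + wo * (counts.tn + counts.fp)
    else:
        smax = wd * (counts.tp + counts.fn) + wo * (counts.tn + counts.fp)
    if smax <= 0:
        raise InputError("S_w denominator is zero (degenerate reference)")
    return s / smax


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if counts.total == 0:
        raise InputError("empty confusion counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def roc_auc(
    scores: np.ndarray, labels: DisorderLabels | np.ndarray
) -> tuple[RocCurve, float]:
    """ROC curve and trapezoidal AUC (disordered = positive class).

    The AUC equals the tie-aware probability that a random disordered
    residue outscores a random ordered one.
    """
    s, y = _known_pairs(scores, labels)
    if len(set(np.unique(y))) < 2:
        raise InputError("ROC requires both classes in the reference")
    fpr, tpr, thr = _skm.roc_curve(y == DISORDERED, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr), auc


def sw_grid(
    scores: np.ndarray,
    labels: DisorderLabels | np.ndarray,
    weights: ClassWeights,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """S_w evaluated at every threshold of the 0..1 step-0.01 grid.

    Vectorized over thresholds via per-class sorted score vectors; exactly
    equivalent to calling ``sw(confusion_at(...))`` at each grid point.
    """
    s, y = _known_pairs(scores, labels)
    if grid is None:
        grid = THRESHOLD_GRID
    s_dis = np.sort(s[y == DISORDERED])
    s_ord = np.sort(s[y == ORDERED])
    n_dis, n_ord = s_dis.size, s_ord.size
    # count of scores >= t   (searchsorted 'left' gives #scores < t)
    tp = n_dis - np.searchsorted(s_dis, grid, side="left")
    fp = n_ord - np.searchsorted(s_ord, grid, side="left")
    fn = n_dis - tp
    tn = n_ord - fp
    wd, wo = weights.w_disorder, weights.w_order
    smax = wd * n_dis + wo * n_ord
    if smax <= 0:
        raise InputError("S_w denominator is zero (degenerate reference)")
    return (wd * tp - wo * fp + wo * tn - wd * fn) / smax


def sww(
    scores: np.ndarray,
    labels: DisorderLabels | np.ndarray,
    weights: ClassWeights,
) -> float:
    """Threshold-averaged S_w: the mean of S_w over the 101-point grid."""
    return float(np.mean(sw_grid(scores, labels, weights)))


def bootstrap_mae(
    per_target_data: Sequence,
    metric: Callable[[Sequence], float],
    fraction: float = 0.8,
    reps: int = 1000,
    seed: int | None = None,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Bootstrap error bar by target subsampling.

    Draws ``reps`` subsamples of ``ceil(fraction * n)`` targets without
    replacement, recomputes ``metric`` on each subsample (the metric pools
    residues itself), and returns ``(mean over reps, mean absolute
    deviation from the full-data score)``. Subsamples on which the metric
    fails (e.g. a single-class draw) are redrawn, up to ``max_retries``
    times each.
    """
    n = len(per_target_data)
    if n < 2:
        raise InputError("bootstrap requires at least 2 targets")
    k = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    full = metric(per_target_data)
    vals = np.empty(reps)
    for r in range(reps):
        for attempt in range(max_retries + 1):
            idx = rng.choice(n, size=k, replace=False)
            try:
                vals[r] = metric([per_target_data[i] for i in idx])
                break
            except (InputError, ValueError, ZeroDivisionError):
                if attempt == max_retries:
                    raise InputError(
                        f"metric failed on {max_retries} consecutive bootstrap draws"
                    )
    return float(vals.mean()), float(np.abs(vals - full).mean())


def wilcoxon_paired(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-target scores.

    Zero differences are dropped first; the exact null distribution is used
    for n <= 25 pairs, the tie-corrected normal approximation otherwise.
    All differences zero returns p = 1.0 (no evidence either way).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired score vectors differ in length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    if nz.size < 5:
        raise InputError(
            f"need >= 5 non-zero paired differences for the signed-rank test, got {nz.size}"
        )
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.pvalue)


def kfold_residue_bins(total_residues: int, k: int = 10, seed: int | None = None) -> np.ndarray:
    """Random assignment of residues into k bins of nearly equal size.

    Returns an int vector of bin indices (0..k-1); bin sizes differ by at
    most one. Residue-level splitting mirrors the cross-validation used to
    calibrate the consensus; for leakage-safe experiments assign whole
    proteins to bins instead (split the per-target list yourself).
    """
    if k < 2:
        raise InputError("k-fold requires k >= 2")
    if total_residues < k:
        raise InputError(f"cannot split {total_residues} residues into {k} bins")
    base, rem = divmod(total_residues, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    bins = np.repeat(np.arange(k), sizes)
    rng = np.random.default_rng(seed)
    rng.shuffle(bins)
    return bins


def write_evaluation_report(path, rows: Sequence[dict]) -> None:
    """Write a per-method evaluation table as TSV.

    Columns: method, Sw, Sw_mae, MCC, AUC, AUC_mae, sensitivity,
    specificity. Missing entries are written as ``-``.
    """
    cols = ["method", "Sw", "Sw_mae", "MCC", "AUC", "AUC_mae", "sensitivity", "specificity"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            out = []
            for c in cols:
                v = row.get(c)
                if v is None:
                    out.append("-")
                elif isinstance(v, float):
                    out.append(f"{v:.3f}")
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")
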