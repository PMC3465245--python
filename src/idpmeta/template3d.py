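"""Disorder prediction from fold-recognition alignment coverage.

A region of a target sequence that no fold-recognition method can align to
a known structure has no detectable structured counterpart — evidence of
intrinsic disorder. Eight method modes (six programs, two of them run in
two modes) each contribute up to ten ranked alignments; every alignment is
classified *good* / *medium* / *poor* from its native score via fixed
per-method cutoffs, and contributes order evidence to the residues it
covers, weighted by one of 24 trainable tier weights (8 modes x 3 tiers).
The per-residue disorder score is one minus the weight-normalized coverage
evidence. The 24 weights are trained with a genetic algorithm maximizing
pooled S_w (or S_ww).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics as _m
from .ga import GAConfig, run_ga
from .types import (
    AlignmentHit,
    ClassWeights,
    DisorderLabels,
    InputError,
    WeightVector,
    class_weights,
)

__all__ = [
    "METHOD_MODES",
    "TIERS",
    "TIER_WEIGHT_NAMES",
    "TierThresholds",
    "DEFAULT_TIER_THRESHOLDS",
    "classify_tier",
    "tier_index",
    "CoverageEvidence",
    "coverage_counts",
    "coverage_evidence",
    "predict_gs3d",
    "train_tier_weights",
    "TemplateCoveragePredictor",
]

#: the 8 fold-recognition method modes, in canonical order.
METHOD_MODES = (
    "psiblast_default",
    "psiblast_nofilter",
    "ffas",
    "mgenthreader",
    "hhsearch_pdb70",
    "hhsearch_cdd",
    "pcons",
    "phyre",
)

TIERS = ("good", "medium", "poor")

#: canonical order of the 24 tier weights: modes x tiers.
TIER_WEIGHT_NAMES = tuple(f"{m}:{t}" for m in METHOD_MODES for t in TIERS)

MAX_HITS_PER_MODE = 10

# method mode -> base program sharing one threshold row
_BASE_METHOD = {
    "psiblast_default": "psiblast",
    "psiblast_nofilter": "psiblast",
    "ffas": "ffas",
    "mgenthreader": "mgenthreader",
    "hhsearch_pdb70": "hhsearch",
    "hhsearch_cdd": "hhsearch",
    "pcons": "pcons",
    "phyre": "phyre",
}


@dataclass(frozen=True)
class TierThresholds:
    """Per-program (good_cutoff, medium_cutoff, direction) triples.

    ``direction`` is "lower_is_better" for e-value-like scores (a hit is
    good if raw < good_cutoff) and "higher_is_better" for score-like ones
    (good if raw > good_cutoff). Boundary values classify to the worse
    tier (strict inequalities). PSI-BLAST and HHsearch share one row
    across their two run modes.
    """

    table: dict[str, tuple[float, float, str]]

    def __post_init__(self) -> None:
        for name, (good, medium, direction) in self.table.items():
            if direction == "lower_is_better":
                ok = good < medium
            elif direction == "higher_is_better":
                ok = good > medium
            else:
                raise InputError(f"{name}: unknown direction {direction!r}")
            if not ok:
                raise InputError(
                    f"{name}: good cutoff must be stricter than medium in the "
                    f"{direction} sense"
                )

    def for_mode(self, method_mode: str) -> tuple[float, float, str]:
        base = _BASE_METHOD.get(method_mode, method_mode)
        try:
            return self.table[base]
        except KeyError:
            raise InputError(f"unknown fold-recognition method mode {method_mode!r}")


#: default alignment-quality cutoffs for the six base programs.
DEFAULT_TIER_THRESHOLDS = TierThresholds(
    {
        "psiblast": (2e-06, 0.023, "lower_is_better"),
        "ffas": (-34.5, -8.5, "lower_is_better"),
        "mgenthreader": (0.65, 0.546, "higher_is_better"),
        "hhsearch": (95.0, 80.0, "higher_is_better"),
        "pcons": (2.17, 1.03, "higher_is_better"),
        "phyre": (0.085, 0.27, "lower_is_better"),
    }
)


def classify_tier(
    method_mode: str,
    raw_score: float,
    thresholds: TierThresholds = DEFAULT_TIER_THRESHOLDS,
) -> str:
    """Classify one hit's raw score as good / medium / poor."""
    good, medium, direction = thresholds.for_mode(method_mode)
    if direction == "lower_is_better":
        if raw_score < good:
            return "good"
        if raw_score < medium:
            return "medium"
    else:
        if raw_score > good:
            return "good"
        if raw_score > medium:
            return "medium"
    return "poor"


def tier_index(method_mode: str, tier: str) -> int:
    """Position of (mode, tier) in the canonical 24-weight vector."""
    try:
        return METHOD_MODES.index(method_mode) * len(TIERS) + TIERS.index(tier)
    except ValueError:
        raise InputError(f"unknown method mode or tier: {method_mode!r}/{tier!r}")


@dataclass(frozen=True)
class CoverageEvidence:
    """Accumulated per-residue order evidence and its normalizer."""

    evidence: np.ndarray
    total_possible: float


def _retained(hits: Sequence[AlignmentHit], max_hits: int) -> list[AlignmentHit]:
    """Keep at most ``max_hits`` hits per method mode, by ascending rank."""
    by_mode: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_mode.setdefault(h.method_mode, []).append(h)
    kept: list[AlignmentHit] = []
    for mode_hits in by_mode.values():
        kept.extend(sorted(mode_hits, key=lambda h: h.rank)[:max_hits])
    return kept


def coverage_counts(
    hits: Sequence[AlignmentHit],
    L: int,
    thresholds: TierThresholds = DEFAULT_TIER_THRESHOLDS,
    max_hits: int = MAX_HITS_PER_MODE,
) -> tuple[np.ndarray, np.ndarray]:
    """Weight-independent coverage summary of one target.

    Returns ``(C, n)`` where ``C[k, r]`` counts retained hits of
    tier-weight class k covering residue r, and ``n[k]`` the retained hits
    of class k. Evidence for any weight vector w is then ``w @ C`` with
    normalizer ``w @ n`` — precomputing this makes GA fitness evaluation a
    matrix product.
    """
    C = np.zeros((len(TIER_WEIGHT_NAMES), L))
    n = np.zeros(len(TIER_WEIGHT_NAMES))
    for h in _retained(hits, max_hits):
        k = tier_index(h.method_mode, classify_tier(h.method_mode, h.raw_score, thresholds))
        C[k] += h.coverage_mask(L)
        n[k] += 1.0
    return C, n


def coverage_evidence(
    hits: Sequence[AlignmentHit],
    L: int,
    tier_weights: WeightVector,
    thresholds: TierThresholds = DEFAULT_TIER_THRESHOLDS,
    max_hits: int = MAX_HITS_PER_MODE,
) -> CoverageEvidence:
    """Per-residue order evidence: sum over retained hits of the hit's
    tier weight, restricted to covered residues."""
    if tier_weights.kind != "tier24":
        raise InputError("coverage evidence needs a tier24 weight vector")
    C, n = coverage_counts(hits, L, thresholds, max_hits)
    w = tier_weights.values
    return CoverageEvidence(evidence=w @ C, total_possible=float(w @ n))


def predict_gs3d(
    hits: Sequence[AlignmentHit],
    L: int,
    tier_weights: WeightVector,
    thresholds: TierThresholds = DEFAULT_TIER_THRESHOLDS,
    max_hits: int = MAX_HITS_PER_MODE,
    no_hit_score: float = 1.0,
) -> np.ndarray:
    """Per-residue disorder scores in [0, 1] from coverage evidence.

    score(r) = 1 - evidence(r) / total_possible. A target with no
    (weighted) hits at all scores ``no_hit_score`` everywhere — by
    default fully disordered, on the premise that the absence of any
    match to known structures is itself evidence of disorder.
    """
    ev = coverage_evidence(hits, L, tier_weights, thresholds, max_hits)
    if ev.total_possible <= 0:
        return np.full(L, float(no_hit_score))
    return 1.0 - ev.evidence / ev.total_possible


def _pooled_fitness_data(
    training: Sequence[tuple[Sequence[AlignmentHit], DisorderLabels]],
    thresholds: TierThresholds,
    max_hits: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, ClassWeights]:
    """Precompute stacked coverage counts for fast pooled GA fitness."""
    if len(training) < 2:
        raise InputError("training requires at least 2 targets")
    labels = [lab for _, lab in training]
    cw = class_weights(labels)  # raises on single-class training data
    C_cols, n_rows, tgt_idx = [], [], []
    for t, (hits, lab) in enumerate(training):
        C, n = coverage_counts(hits, lab.L, thresholds, max_hits)
        C_cols.append(C)
        n_rows.append(n)
        tgt_idx.append(np.full(lab.L, t))
    return (
        np.hstack(C_cols),
        np.vstack(n_rows),
        np.concatenate(tgt_idx),
        np.concatenate([lab.states for lab in labels]),
        cw,
    )


def _scores_from_weights(
    w: np.ndarray,
    C_all: np.ndarray,
    n_all: np.ndarray,
    tgt_idx: np.ndarray,
    no_hit_score: float,
) -> np.ndarray:
    totals = n_all @ w  # per-target normalizers
    ev = w @ C_all
    per_res_total = totals[tgt_idx]
    out = np.full(ev.shape, float(no_hit_score))
    ok = per_res_total > 0
    out[ok] = 1.0 - ev[ok] / per_res_total[ok]
    return out


def train_tier_weights(
    training: Sequence[tuple[Sequence[AlignmentHit], DisorderLabels]],
    fitness: str = "sw",
    thresholds: TierThresholds = DEFAULT_TIER_THRESHOLDS,
    ga_cfg: GAConfig | None = None,
    seed: int | None = None,
    max_hits: int = MAX_HITS_PER_MODE,
    no_hit_score: float = 1.0,
    return_history: bool = False,
):
    """GA training of the 24 tier weights.

    ``training`` is a list of (hits, labels) pairs. Fitness of a genome is
    the pooled best-threshold S_w of its predictions (``fitness="sw"``) or
    the pooled S_ww on the raw scores (``fitness="sww"``). Deterministic
    given seed; the best-fitness trace is non-decreasing (elitism).
    """
    if fitness not in ("sw", "sww"):
        raise InputError(f"fitness must be 'sw' or 'sww', got {fitness!r}")
    C_all, n_all, tgt_idx, states, cw = _pooled_fitness_data(training, thresholds, max_hits)

    def fit_fn(w: np.ndarray) -> float:
        scores = _scores_from_weights(w, C_all, n_all, tgt_idx, no_hit_score)
        grid = _m.sw_grid(scores, states, cw)
        return float(grid.max() if fitness == "sw" else grid.mean())

    best, history = run_ga(fit_fn, n_genes=24, cfg=ga_cfg, seed=seed)
    wv = WeightVector(TIER_WEIGHT_NAMES, best, "tier24")
    return (wv, history) if return_history else wv


class TemplateCoveragePredictor(BaseEstimator):
    """Fold-recognition coverage disorder predictor with GA-trained weights.

    ``X`` is a sequence of per-target hit lists (each a sequence of
    :class:`AlignmentHit`); ``y`` the matching :class:`DisorderLabels`
    (which also provide target lengths).

    Attributes (after fit)
    ----------------------
    tier_weights_ : WeightVector (tier24)
    threshold_ : float — S_w-optimal decision threshold on training scores
    fitness_history_ : np.ndarray — best GA fitness per generation
    class_weights_ : ClassWeights
    """

    def __init__(
        self,
        fitness: str = "sw",
        thresholds: TierThresholds = DEFAULT_TIER_THRESHOLDS,
        max_hits: int = MAX_HITS_PER_MODE,
        no_hit_score: float = 1.0,
        ga_cfg: GAConfig | None = None,
        random_state: int | None = None,
    ) -> None:
        self.fitness = fitness
        self.thresholds = thresholds
        self.max_hits = max_hits
        self.no_hit_score = no_hit_score
        self.ga_cfg = ga_cfg
        self.random_state = random_state

    def fit(
        self,
        X: Sequence[Sequence[AlignmentHit]],
        y: Sequence[DisorderLabels],
    ) -> "TemplateCoveragePredictor":
        if len(X) != len(y):
            raise InputError("X and y differ in length")
        training = list(zip(X, y))
        self.tier_weights_, self.fitness_history_ = train_tier_weights(
            training,
            fitness=self.fitness,
            thresholds=self.thresholds,
            ga_cfg=self.ga_cfg,
            seed=self.random_state,
            max_hits=self.max_hits,
            no_hit_score=self.no_hit_score,
            return_history=True,
        )
        self.class_weights_ = class_weights(list(y))
        pooled = np.concatenate(
            [self._scores_one(hits, lab.L) for hits, lab in training]
        )
        states = np.concatenate([lab.states for lab in y])
        from .consensus import select_threshold

        self.threshold_ = select_threshold(pooled, states, self.class_weights_)
        return self

    def _scores_one(self, hits: Sequence[AlignmentHit], L: int) -> np.ndarray:
        return predict_gs3d(
            hits, L, self.tier_weights_, self.thresholds, self.max_hits, self.no_hit_score
        )

    def predict_scores(
        self, X: Sequence[Sequence[AlignmentHit]], lengths: Sequence[int]
    ) -> list[np.ndarray]:
        if not hasattr(self, "tier_weights_"):
            raise InputError("estimator is not fitted yet; call fit first")
        return [self._scores_one(hits, L) for hits, L in zip(X, lengths)]

    def predict(
        self, X: Sequence[Sequence[AlignmentHit]], lengths: Sequence[int]
    ) -> list[str]:
        from .consensus import _calls_from_scores, repair

        return [
            repair(_calls_from_scores(s, self.threshold_))
            for s in self.predict_scores(X, lengths)
        ]
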