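"""Fusion of the consensus and fold-recognition coverage channels.

The combined predictor mixes the continuous consensus score c(r) with the
coverage-based disorder score t(r) as (a*c + b*t)/(a + b). The two channel
weights are trained jointly with the 24 tier weights as one 26-gene GA
genome; the fitness is pooled best-threshold S_w, or pooled S_ww for the
variant that targets threshold-free performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics as _m
from .consensus import _calls_from_scores, repair, select_threshold
from .ga import GAConfig, run_ga
from .template3d import (
    DEFAULT_TIER_THRESHOLDS,
    MAX_HITS_PER_MODE,
    TIER_WEIGHT_NAMES,
    TierThresholds,
    _pooled_fitness_data,
    _scores_from_weights,
)
from .types import (
    AlignmentHit,
    DisorderLabels,
    InputError,
    WeightVector,
    class_weights,
)

__all__ = ["CombinedModel", "combine", "train_combined", "CombinedDisorderPredictor"]

COMPONENT_NAMES = ("component:consensus", "component:template")


@dataclass(frozen=True)
class CombinedModel:
    """Trained state of the two-channel predictor."""

    tier_weights: WeightVector  # kind tier24
    component_weights: tuple[float, float]  # (a_consensus, b_template)
    threshold: float
    fitness_kind: str

    def __post_init__(self) -> None:
        a, b = self.component_weights
        if a < 0 or b < 0 or a + b <= 0:
            raise InputError("component weights must be >= 0 with a + b > 0")
        if self.fitness_kind not in ("sw", "sww"):
            raise InputError(f"fitness_kind must be 'sw' or 'sww', got {self.fitness_kind!r}")

    def genome(self) -> WeightVector:
        """The full 26-gene vector (24 tier weights + 2 component weights)."""
        return WeightVector(
            TIER_WEIGHT_NAMES + COMPONENT_NAMES,
            np.concatenate([self.tier_weights.values, self.component_weights]),
            "tier24_plus_components",
        )


def combine(
    consensus_scores: np.ndarray,
    template_scores: np.ndarray,
    component_weights: tuple[float, float],
) -> np.ndarray:
    """Convex combination (a*c + b*t)/(a + b) of the two channels."""
    a, b = component_weights
    if a < 0 or b < 0:
        raise InputError("component weights must be non-negative")
    if a + b <= 0:
        raise InputError("component weights must not both be zero")
    c = np.asarray(consensus_scores, dtype=float)
    t = np.asarray(template_scores, dtype=float)
    if c.shape != t.shape:
        raise InputError("channel score vectors differ in length")
    return (a * c + b * t) / (a + b)


def train_combined(
    training: Sequence[tuple[np.ndarray, Sequence[AlignmentHit], DisorderLabels]],
    fitness_kind: str = "sw",
    thresholds: TierThresholds = DEFAULT_TIER_THRESHOLDS,
    ga_cfg: GAConfig | None = None,
    seed: int | None = None,
    max_hits: int = MAX_HITS_PER_MODE,
    no_hit_score: float = 1.0,
) -> CombinedModel:
    """Joint GA training of tier and component weights.

    ``training`` lists per-target (consensus_scores, hits, labels)
    triples. The 26-gene genome holds the 24 tier weights followed by
    (a, b); genomes with a + b ~ 0 are assigned the worst fitness rather
    than raising. After the GA, the decision threshold is selected on the
    pooled training scores of the best genome.
    """
    if fitness_kind not in ("sw", "sww"):
        raise InputError(f"fitness_kind must be 'sw' or 'sww', got {fitness_kind!r}")
    hits_labels = [(hits, lab) for _, hits, lab in training]
    C_all, n_all, tgt_idx, states, cw = _pooled_fitness_data(hits_labels, thresholds, max_hits)
    cons = np.concatenate([np.asarray(c, dtype=float) for c, _, _ in training])
    if cons.size != states.size:
        raise InputError("consensus score vectors do not match label lengths")

    def combined_scores(genome: np.ndarray) -> np.ndarray | None:
        w, (a, b) = genome[:24], genome[24:]
        if a + b < 1e-12:
            return None
        t = _scores_from_weights(w, C_all, n_all, tgt_idx, no_hit_score)
        return (a * cons + b * t) / (a + b)

    def fit_fn(genome: np.ndarray) -> float:
        s = combined_scores(genome)
        if s is None:
            return -1.0
        grid = _m.sw_grid(s, states, cw)
        return float(grid.max() if fitness_kind == "sw" else grid.mean())

    best, _ = run_ga(fit_fn, n_genes=26, cfg=ga_cfg, seed=seed)
    pooled = combined_scores(best)
    if pooled is None:  # pragma: no cover - GA cannot select an invalid elite
        raise InputError("GA returned a degenerate component weighting")
    threshold = select_threshold(pooled, states, cw)
    return CombinedModel(
        tier_weights=WeightVector(TIER_WEIGHT_NAMES, best[:24], "tier24"),
        component_weights=(float(best[24]), float(best[25])),
        threshold=threshold,
        fitness_kind=fitness_kind,
    )


class CombinedDisorderPredictor(BaseEstimator):
    """Two-channel disorder predictor (consensus + template coverage).

    ``X`` is a sequence of per-target ``(consensus_scores, hits)`` pairs —
    the consensus channel is produced upstream by
    :class:`~idpmeta.consensus.ConsensusDisorderPredictor` — and ``y`` the
    matching labels. ``fitness="sww"`` selects the variant trained on the
    threshold-averaged score.

    Attributes (after fit): ``model_`` (:class:`CombinedModel`),
    ``class_weights_``.
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
        X: Sequence[tuple[np.ndarray, Sequence[AlignmentHit]]],
        y: Sequence[DisorderLabels],
    ) -> "CombinedDisorderPredictor":
        if len(X) != len(y):
            raise InputError("X and y differ in length")
        training = [(c, hits, lab) for (c, hits), lab in zip(X, y)]
        self.model_ = train_combined(
            training,
            fitness_kind=self.fitness,
            thresholds=self.thresholds,
            ga_cfg=self.ga_cfg,
            seed=self.random_state,
            max_hits=self.max_hits,
            no_hit_score=self.no_hit_score,
        )
        self.class_weights_ = class_weights(list(y))
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise InputError("estimator is not fitted yet; call fit first")

    def predict_scores(
        self,
        X: Sequence[tuple[np.ndarray, Sequence[AlignmentHit]]],
        lengths: Sequence[int],
    ) -> list[np.ndarray]:
        self._check_fitted()
        from .template3d import predict_gs3d

        out = []
        for (c, hits), L in zip(X, lengths):
            t = predict_gs3d(
                hits, L, self.model_.tier_weights, self.thresholds,
                self.max_hits, self.no_hit_score,
            )
            out.append(combine(c, t, self.model_.component_weights))
        return out

    def predict(
        self,
        X: Sequence[tuple[np.ndarray, Sequence[AlignmentHit]]],
        lengths: Sequence[int],
    ) -> list[str]:
        return [
            repair(_calls_from_scores(s, self.model_.threshold))
            for s in self.predict_scores(X, lengths)
        ]
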