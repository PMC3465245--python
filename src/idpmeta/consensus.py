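"""Accuracy-weighted consensus disorder prediction (BinCons / FloatCons).

The consensus score of a residue is the weight-normalized sum of the
per-method scores, where each method's weight is its own S_w measured on a
calibration set ("the accuracy of the given method"). Two variants:

* **binary mode** (BinCons): every column is reduced to a two-state call
  and encoded disordered = 1, ordered = 0.01 (a small positive value
  instead of 0 guards against zero denominators);
* **continuous mode** (FloatCons): continuous columns contribute their raw
  [0, 1] scores; binary columns are encoded as above.

After the weighted sum, a terminal correction multiplies scores within 15
residues of either chain end (termini are, on average, more disordered),
the decision threshold is the S_w-optimal point on a 0.01 grid, and a
repair filter removes isolated short (<= 3 residue) disorder calls inside
long ordered stretches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics as _m
from .types import (
    DISORDERED,
    ORDERED,
    UNKNOWN,
    ClassWeights,
    DisorderLabels,
    InputError,
    PredictionProfile,
    WeightVector,
    class_weights,
)

__all__ = [
    "TerminalCorrection",
    "ConsensusConfig",
    "encode_binary",
    "weighted_consensus",
    "method_sw_weights",
    "estimate_terminal_correction",
    "apply_terminal_correction",
    "select_threshold",
    "repair",
    "predict_consensus",
    "ConsensusDisorderPredictor",
]

N_PROXIMAL = 15


@dataclass(frozen=True)
class TerminalCorrection:
    """Multiplicative score correction near the chain termini.

    ``factors_nterm[i]`` multiplies the score of the residue at offset
    i+1 from the N-terminus (1-based offsets 1..15), ``factors_cterm``
    likewise from the C-terminus. Interior residues are untouched
    (implicit factor 1).
    """

    factors_nterm: np.ndarray
    factors_cterm: np.ndarray
    n_proximal: int = N_PROXIMAL

    def __post_init__(self) -> None:
        fn = np.asarray(self.factors_nterm, dtype=float)
        fc = np.asarray(self.factors_cterm, dtype=float)
        object.__setattr__(self, "factors_nterm", fn)
        object.__setattr__(self, "factors_cterm", fc)
        if fn.shape != (self.n_proximal,) or fc.shape != (self.n_proximal,):
            raise InputError(f"terminal correction needs {self.n_proximal} factors per end")
        if (fn <= 0).any() or (fc <= 0).any():
            raise InputError("terminal correction factors must be positive")

    @classmethod
    def identity(cls, n_proximal: int = N_PROXIMAL) -> "TerminalCorrection":
        ones = np.ones(n_proximal)
        return cls(ones, ones.copy(), n_proximal)


@dataclass(frozen=True)
class ConsensusConfig:
    """Knobs of the consensus pipeline (defaults match the published setup)."""

    mode: str = "continuous"  # "binary" -> BinCons, "continuous" -> FloatCons
    binary_positive: float = 1.0
    binary_negative: float = 0.01
    threshold: float = 0.5
    repair_max_run: int = 3
    repair_window: int = 5
    native_threshold: float = 0.5  # binarization point for continuous columns in binary mode
    strict_threshold: bool = False  # call disordered on score > t instead of >= t

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "continuous"):
            raise InputError(f"mode must be 'binary' or 'continuous', got {self.mode!r}")
        if self.binary_negative <= 0:
            raise InputError("binary_negative must be > 0 (division-by-zero guard)")
        if not 0.0 <= self.threshold <= 1.0:
            raise InputError("threshold must lie in [0, 1]")
        if self.repair_max_run >= self.repair_window:
            raise InputError("repair_max_run must be smaller than repair_window")


def encode_binary(profile: PredictionProfile, cfg: ConsensusConfig) -> PredictionProfile:
    """Encode two-state calls as scores: disordered -> 1.0, ordered -> 0.01.

    Binary columns must carry calls encoded 1.0 (disordered) / 0.0
    (ordered); anything else raises, naming column and row. Continuous
    columns pass through untouched in continuous mode and are binarized at
    the method's native call threshold in binary mode. NaN stays missing.
    """
    scores = profile.scores.copy()
    for j, name in enumerate(profile.methods):
        col = scores[:, j]
        present = ~np.isnan(col)
        if profile.is_binary[j]:
            bad = present & (col != 0.0) & (col != 1.0)
            if bad.any():
                row = int(np.argmax(bad)) + 1
                raise InputError(
                    f"profile {profile.id!r}, column {name!r}, residue {row}: "
                    f"binary call must be 0 or 1, got {col[row - 1]!r}"
                )
            calls = col == 1.0
        elif cfg.mode == "binary":
            calls = col >= cfg.native_threshold
        else:
            continue
        col[present & calls] = cfg.binary_positive
        col[present & ~calls] = cfg.binary_negative
    return replace(
        profile,
        scores=scores,
        methods=list(profile.methods),
        is_binary=profile.is_binary.copy(),
    )


def weighted_consensus(profile: PredictionProfile, method_weights: WeightVector) -> np.ndarray:
    """Per-residue accuracy-weighted mean of method scores.

    score(r) = sum_m w_m * s_m(r) / sum_m w_m, the sums running over
    methods with a non-missing value at r (per-residue re-normalization).
    Residues missing every method come out NaN.
    """
    wmap = method_weights.as_dict()
    missing = [m for m in profile.methods if m not in wmap]
    if missing:
        raise InputError(f"no weight provided for method(s): {missing}")
    w = np.array([wmap[m] for m in profile.methods])
    if (w < 0).any() or not (w > 0).any():
        raise InputError("method weights must be >= 0 with at least one > 0")
    s = profile.scores
    present = ~np.isnan(s)
    num = np.nansum(s * w, axis=1)
    den = present @ w
    out = np.full(profile.L, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, 0.0, 1.0, out=out)


def method_sw_weights(
    profiles: Sequence[PredictionProfile],
    labels: Sequence[DisorderLabels],
    cfg: ConsensusConfig | None = None,
    min_weight: float = 0.0,
) -> WeightVector:
    """Per-method consensus weights: each method's best pooled S_w.

    Scores are pooled over the calibration targets (after binary
    encoding), S_w is maximized over the 0.01 threshold grid, and negative
    values are floored at ``min_weight`` (a negative weight would invert a
    predictor). Methods must be named identically across profiles.
    """
    cfg = cfg or ConsensusConfig()
    if len(profiles) != len(labels):
        raise InputError("profiles and labels collections differ in length")
    methods = list(profiles[0].methods)
    for p in profiles[1:]:
        if list(p.methods) != methods:
            raise InputError("all profiles must share the same method columns")
    encoded = [encode_binary(p, cfg) for p in profiles]
    pooled_states = np.concatenate([lab.states for lab in labels])
    weights = class_weights(list(labels))
    values = []
    for j, name in enumerate(methods):
        col = np.concatenate([p.scores[:, j] for p in encoded])
        best = float(np.max(_m.sw_grid(col, pooled_states, weights)))
        values.append(max(best, min_weight, 0.0))
    if not any(v > 0 for v in values):
        raise InputError("every method has non-positive calibration S_w; no usable weights")
    return WeightVector(tuple(methods), np.array(values), "consensus_method_weights")


def estimate_terminal_correction(
    labels: Sequence[DisorderLabels],
    n_proximal: int = N_PROXIMAL,
    eps: float = 1e-6,
) -> TerminalCorrection:
    """Terminal correction factors from reference disorder statistics.

    Factor at terminal offset i (1..15 from each end) is
    P(disordered | offset i) / P(disordered | interior), floored at a
    small positive epsilon. Chains of <= 2*15 residues carry no
    unambiguous interior and are skipped with a warning.
    """
    min_len = 2 * n_proximal + 1
    cnt_n = np.zeros(n_proximal)
    dis_n = np.zeros(n_proximal)
    cnt_c = np.zeros(n_proximal)
    dis_c = np.zeros(n_proximal)
    cnt_int = dis_int = 0.0
    used = 0
    for lab in labels:
        L = lab.L
        if L < min_len:
            warnings.warn(
                f"terminal correction: skipping {lab.id!r} (L={L} < {min_len})",
                stacklevel=2,
            )
            continue
        used += 1
        st = lab.states
        known = st != UNKNOWN
        dis = st == DISORDERED
        head, tail = slice(0, n_proximal), slice(L - n_proximal, L)
        cnt_n += known[head]
        dis_n += dis[head]
        cnt_c += known[tail][::-1]
        dis_c += dis[tail][::-1]
        cnt_int += known[n_proximal : L - n_proximal].sum()
        dis_int += dis[n_proximal : L - n_proximal].sum()
    if used == 0:
        raise InputError(f"no reference chains of length >= {min_len}")
    if cnt_int == 0 or dis_int == 0:
        raise InputError("interior disorder frequency is zero; correction uninformative")
    p_int = dis_int / cnt_int
    with np.errstate(invalid="ignore", divide="ignore"):
        fn = np.where(cnt_n > 0, dis_n / np.maximum(cnt_n, 1), 0.0) / p_int
        fc = np.where(cnt_c > 0, dis_c / np.maximum(cnt_c, 1), 0.0) / p_int
    return TerminalCorrection(np.maximum(fn, eps), np.maximum(fc, eps), n_proximal)


def apply_terminal_correction(scores: np.ndarray, corr: TerminalCorrection) -> np.ndarray:
    """Multiply terminal-proximal scores by their offset factor, clip to [0, 1].

    Within ``n_proximal`` residues of a terminus the offset factor applies;
    for chains short enough that the windows overlap, the nearer terminus
    wins and ties go to the N-terminal factor. NaN passes through.
    """
    scores = np.asarray(scores, dtype=float)
    L = scores.size
    factors = np.ones(L)
    k = corr.n_proximal
    for i in range(L):
        off_n = i + 1
        off_c = L - i
        if off_n <= k and (off_n <= off_c or off_c > k):
            factors[i] = corr.factors_nterm[off_n - 1]
        elif off_c <= k:
            factors[i] = corr.factors_cterm[off_c - 1]
    return np.clip(scores * factors, 0.0, 1.0)


def select_threshold(
    scores: np.ndarray,
    labels: DisorderLabels | np.ndarray,
    weights: ClassWeights,
) -> float:
    """The S_w-maximizing decision threshold on the 0.01 grid.

    Ties are broken toward the lowest threshold (np.argmax returns the
    first maximum on the ascending grid), so constant scores yield 0.0.
    """
    grid_sw = _m.sw_grid(scores, labels, weights)
    return float(_m.THRESHOLD_GRID[int(np.argmax(grid_sw))])


def repair(calls: str, max_run: int = 3, window: int = 5) -> str:
    """Smoothing filter on a two-state call string over {D, -}.

    Every maximal run of D of length <= ``max_run`` flanked by order on
    BOTH sides is converted to order; runs touching a terminus are kept.
    Idempotent, and never converts order to disorder.
    """
    if max_run >= window:
        raise InputError("max_run must be smaller than the smoothing window")
    bad = set(calls) - {"D", "-"}
    if bad:
        raise InputError(f"calls must be over {{D, -}}, found {sorted(bad)}")
    out = list(calls)
    i = 0
    n = len(calls)
    while i < n:
        if calls[i] == "D":
            j = i
            while j < n and calls[j] == "D":
                j += 1
            interior = i > 0 and j < n
            if interior and (j - i) <= max_run:
                out[i:j] = ["-"] * (j - i)
            i = j
        else:
            i += 1
    return "".join(out)


def _calls_from_scores(scores: np.ndarray, threshold: float, strict: bool = False) -> str:
    """Two-state call string; residues with missing scores are called ordered."""
    pred = (scores > threshold) if strict else (scores >= threshold)
    pred = np.where(np.isnan(scores), False, pred)
    return "".join("D" if p else "-" for p in pred)


def predict_consensus(
    profile: PredictionProfile,
    method_weights: WeightVector,
    corr: TerminalCorrection | None,
    cfg: ConsensusConfig,
) -> tuple[np.ndarray, str]:
    """Full consensus chain: encode -> weighted sum -> terminal correction ->
    threshold -> repair. Returns (continuous scores, final call string)."""
    encoded = encode_binary(profile, cfg)
    scores = weighted_consensus(encoded, method_weights)
    if corr is not None:
        scores = apply_terminal_correction(scores, corr)
    calls = _calls_from_scores(scores, cfg.threshold, cfg.strict_threshold)
    calls = repair(calls, cfg.repair_max_run, cfg.repair_window)
    return scores, calls


class ConsensusDisorderPredictor(BaseEstimator):
    """Accuracy-weighted consensus of per-residue disorder predictors.

    scikit-learn style estimator. ``X`` is a sequence of
    :class:`PredictionProfile` (one per target) sharing the same method
    columns; ``y`` a matching sequence of :class:`DisorderLabels`.

    Parameters
    ----------
    mode : {"continuous", "binary"}
        FloatCons-style (use continuous scores where available) or
        BinCons-style (reduce everything to 1 / 0.01 encoded calls).
    use_terminal_correction : bool
        Estimate and apply the terminal disorder-enrichment correction.
    min_weight : float
        Floor for calibration S_w weights (methods at the floor with
        weight 0 are effectively excluded).

    Attributes (after fit)
    ----------------------
    method_weights_ : WeightVector
        Per-method S_w weights from the calibration data.
    terminal_correction_ : TerminalCorrection
        Estimated terminal factors (identity if disabled).
    threshold_ : float
        S_w-optimal decision threshold on the calibration consensus.
    class_weights_ : ClassWeights
        Pooled calibration class weights.
    """

    def __init__(
        self,
        mode: str = "continuous",
        binary_positive: float = 1.0,
        binary_negative: float = 0.01,
        repair_max_run: int = 3,
        repair_window: int = 5,
        native_threshold: float = 0.5,
        use_terminal_correction: bool = True,
        min_weight: float = 0.0,
        strict_threshold: bool = False,
    ) -> None:
        self.mode = mode
        self.binary_positive = binary_positive
        self.binary_negative = binary_negative
        self.repair_max_run = repair_max_run
        self.repair_window = repair_window
        self.native_threshold = native_threshold
        self.use_terminal_correction = use_terminal_correction
        self.min_weight = min_weight
        self.strict_threshold = strict_threshold

    def _config(self, threshold: float = 0.5) -> ConsensusConfig:
        return ConsensusConfig(
            mode=self.mode,
            binary_positive=self.binary_positive,
            binary_negative=self.binary_negative,
            threshold=threshold,
            repair_max_run=self.repair_max_run,
            repair_window=self.repair_window,
            native_threshold=self.native_threshold,
            strict_threshold=self.strict_threshold,
        )

    def fit(
        self,
        X: Sequence[PredictionProfile],
        y: Sequence[DisorderLabels],
    ) -> "ConsensusDisorderPredictor":
        if len(X) == 0 or len(X) != len(y):
            raise InputError("fit needs matching non-empty profile and label collections")
        for p, lab in zip(X, y):
            if p.L != lab.L:
                raise InputError(f"length mismatch for {p.id!r}: profile {p.L}, labels {lab.L}")
        cfg = self._config()
        self.class_weights_ = class_weights(list(y))
        self.method_weights_ = method_sw_weights(X, y, cfg, self.min_weight)
        if self.use_terminal_correction:
            self.terminal_correction_ = estimate_terminal_correction(y)
        else:
            self.terminal_correction_ = TerminalCorrection.identity()
        pooled_scores = np.concatenate(
            [self._raw_scores(p, cfg) for p in X]
        )
        pooled_states = np.concatenate([lab.states for lab in y])
        self.threshold_ = select_threshold(pooled_scores, pooled_states, self.class_weights_)
        return self

    def _raw_scores(self, profile: PredictionProfile, cfg: ConsensusConfig) -> np.ndarray:
        scores = weighted_consensus(encode_binary(profile, cfg), self.method_weights_)
        return apply_terminal_correction(scores, self.terminal_correction_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "method_weights_"):
            raise InputError("estimator is not fitted yet; call fit first")

    def predict_scores(self, X: Sequence[PredictionProfile]) -> list[np.ndarray]:
        """Continuous consensus scores per target (after terminal correction)."""
        self._check_fitted()
        cfg = self._config(self.threshold_)
        return [self._raw_scores(p, cfg) for p in X]

    def predict(self, X: Sequence[PredictionProfile]) -> list[str]:
        """Final two-state call strings (thresholded and repaired)."""
        self._check_fitted()
        cfg = self._config(self.threshold_)
        out = []
        for p in X:
            _, calls = predict_consensus(p, self.method_weights_, self.terminal_correction_, cfg)
            out.append(calls)
        return out

    def score(self, X: Sequence[PredictionProfile], y: Sequence[DisorderLabels]) -> float:
        """Pooled S_w of the thresholded predictions against ``y``."""
        self._check_fitted()
        pooled = np.concatenate(self.predict_scores(X))
        states = np.concatenate([lab.states for lab in y])
        counts = _m.confusion_at(pooled, states, self.threshold_, self.strict_threshold)
        return _m.sw(counts, class_weights(list(y)))
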