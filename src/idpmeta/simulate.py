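"""Synthetic fixtures: labeled sequences, predictor profiles, and
fold-recognition hits with controlled statistical structure.

The generator emulates the features of real disorder benchmarks that the
pipeline exercises: disorder occurs in contiguous segments (so the repair
filter and terminal correction see runs, not i.i.d. noise), chain termini
are enriched for disorder by a configurable multiplier, per-method scores
follow Beta distributions whose separation sets the method's AUC, and
fold-recognition hits preferentially cover ordered segments, leaking into
disordered ones at a configured rate, with raw scores drawn inside the
tier bands of the classification table.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .template3d import METHOD_MODES, TIER_WEIGHT_NAMES, TIERS, tier_index
from .types import (
    DISORDERED,
    ORDERED,
    AlignmentHit,
    DisorderLabels,
    InputError,
    PredictionProfile,
    SequenceRecord,
    WeightVector,
)

__all__ = [
    "MethodScoreModel",
    "SimConfig",
    "default_method_models",
    "default_true_tier_weights",
    "TIER_SCORE_BANDS",
    "gen_labels",
    "sim_profile",
    "sim_profiles",
    "sim_hits",
    "write_fixture_bundle",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class MethodScoreModel:
    """Beta score model for one simulated predictor.

    Disordered residues score ~ Beta(alpha_dis, beta_dis), ordered ones
    ~ Beta(alpha_ord, beta_ord); the separation of the two distributions
    sets the method's AUC. ``is_binary`` emits two-state calls obtained
    by thresholding the latent score at 0.5.
    """

    alpha_dis: float
    beta_dis: float
    alpha_ord: float
    beta_ord: float
    is_binary: bool = False

    def __post_init__(self) -> None:
        if min(self.alpha_dis, self.beta_dis, self.alpha_ord, self.beta_ord) <= 0:
            raise InputError("Beta parameters must be positive")


def default_method_models() -> dict[str, MethodScoreModel]:
    """Thirteen simulated primary predictors of heterogeneous accuracy.

    Shape parameters span AUCs of roughly 0.71 to 0.86 (the range
    published single-method disorder benchmarks occupy); four methods are
    binary-only.
    """
    shapes = [1.9, 1.95, 2.0, 2.05, 2.1, 2.15, 2.2, 2.25, 2.3, 2.35, 2.4, 2.5, 2.6]
    models = {}
    for i, a in enumerate(shapes, start=1):
        models[f"sim{i:02d}"] = MethodScoreModel(
            alpha_dis=a, beta_dis=1.3, alpha_ord=1.3, beta_ord=a,
            is_binary=(i % 4 == 0),
        )
    return models


def default_true_tier_weights() -> WeightVector:
    """Generative tier weights: good alignments are strongly informative,
    medium moderately, poor hardly at all; some spread across methods."""
    goods = [0.95, 0.90, 0.85, 0.80, 0.90, 0.85, 0.75, 0.70]
    mediums = [0.50, 0.45, 0.40, 0.35, 0.45, 0.40, 0.30, 0.35]
    poors = [0.05] * 8
    vals = np.array([v for trio in zip(goods, mediums, poors) for v in trio])
    return WeightVector(TIER_WEIGHT_NAMES, vals, "tier24")


#: raw-score sampling bands per base program and tier; disjoint by
#: construction and strictly inside the classification cutoffs, so
#: classify_tier recovers the emitted tier exactly.
TIER_SCORE_BANDS: dict[str, dict[str, tuple[float, float]]] = {
    "psiblast": {"good": (1e-12, 1e-6), "medium": (1e-5, 0.02), "poor": (0.03, 10.0)},
    "ffas": {"good": (-80.0, -35.0), "medium": (-30.0, -9.0), "poor": (-8.0, -0.1)},
    "mgenthreader": {"good": (0.66, 0.95), "medium": (0.55, 0.64), "poor": (0.05, 0.54)},
    "hhsearch": {"good": (95.5, 100.0), "medium": (81.0, 94.5), "poor": (5.0, 79.0)},
    "pcons": {"good": (2.2, 4.0), "medium": (1.1, 2.1), "poor": (0.05, 1.0)},
    "phyre": {"good": (0.0005, 0.08), "medium": (0.1, 0.26), "poor": (0.3, 1.0)},
}

_LOG_UNIFORM_METHODS = {"psiblast", "phyre"}  # e-value-like scales

_BASE_OF_MODE = {
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
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults mirror the composition of the combined training data the
    consensus was calibrated on: 23.45% disordered residues, chains of
    50-300 residues, disorder in geometric segments of mean length 12,
    and a two-fold disorder enrichment in the 15 proximal residues of
    each terminus.
    """

    n_targets: int = 50
    length_range: tuple[int, int] = (50, 300)
    disorder_fraction: float = 0.2345
    segment_mean_length: float = 12.0
    terminal_enrichment: float = 2.0
    n_proximal: int = 15
    method_models: dict[str, MethodScoreModel] = field(default_factory=default_method_models)
    hits_per_mode: int = 10
    tier_emission_probs: tuple[float, float, float] = (0.3, 0.3, 0.4)
    leak_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.disorder_fraction < 1.0:
            raise InputError("disorder_fraction must lie in (0, 1)")
        if self.segment_mean_length < 1 or self.terminal_enrichment <= 0:
            raise InputError("segment mean length >= 1 and enrichment > 0 required")
        if self.length_range[0] < 2 or self.length_range[1] < self.length_range[0]:
            raise InputError("invalid length_range")
        if abs(sum(self.tier_emission_probs) - 1.0) > 1e-9:
            raise InputError("tier emission probabilities must sum to 1")
        if not 0.0 <= self.leak_rate <= 1.0:
            raise InputError("leak_rate must lie in [0, 1]")


def _base_fraction(cfg: SimConfig) -> float:
    """Segment-process disorder fraction, compensated so that the overall
    realized fraction (after terminal enrichment) matches the target."""
    mean_len = 0.5 * (cfg.length_range[0] + cfg.length_range[1])
    term_frac = min(1.0, 2 * cfg.n_proximal / mean_len)
    f0 = cfg.disorder_fraction / (1.0 + term_frac * (cfg.terminal_enrichment - 1.0))
    if not 0.0 < f0 < 1.0:
        raise InputError("infeasible config: terminal enrichment vs disorder fraction")
    mean_ord = cfg.segment_mean_length * (1.0 - f0) / f0
    if mean_ord < 1.0:
        raise InputError("infeasible config: disorder fraction too high for segment lengths")
    return f0


def gen_labels(
    cfg: SimConfig, seed: int | None = None
) -> list[tuple[SequenceRecord, DisorderLabels]]:
    """Sequences with planted disorder segments.

    Chains alternate ordered and disordered geometric segments; the 15
    proximal residues of each terminus are additionally flipped
    ordered -> disordered at a rate chosen so that their disorder
    probability is ``terminal_enrichment`` times the interior one.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    f0 = _base_fraction(cfg)
    mean_dis = cfg.segment_mean_length
    mean_ord = mean_dis * (1.0 - f0) / f0
    # flip rate q: f0 + (1 - f0) q = enrichment * f0, clipped to a probability
    q = np.clip((cfg.terminal_enrichment - 1.0) * f0 / (1.0 - f0), 0.0, 1.0)
    out = []
    for t in range(cfg.n_targets):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        states = np.empty(L, dtype=np.int8)
        pos = 0
        disordered = rng.random() < f0
        while pos < L:
            mean = mean_dis if disordered else mean_ord
            run = int(rng.geometric(min(1.0, 1.0 / mean)))
            states[pos : pos + run] = DISORDERED if disordered else ORDERED
            pos += run
            disordered = not disordered
        k = min(cfg.n_proximal, L)
        term = np.zeros(L, dtype=bool)
        term[:k] = True
        term[L - k :] = True
        flip = term & (states == ORDERED) & (rng.random(L) < q)
        states[flip] = DISORDERED
        seq = "".join(rng.choice(_AA, size=L))
        rec = SequenceRecord(f"sim_{t + 1:04d}", seq)
        out.append((rec, DisorderLabels(rec.id, states)))
    return out


def sim_profile(
    labels: DisorderLabels,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> PredictionProfile:
    """Simulated predictor score columns for one target."""
    L = labels.L
    names = list(cfg.method_models)
    scores = np.empty((L, len(names)))
    is_binary = np.zeros(len(names), dtype=bool)
    dis = labels.states == DISORDERED
    for j, name in enumerate(names):
        m = cfg.method_models[name]
        col = np.where(
            dis,
            rng.beta(m.alpha_dis, m.beta_dis, size=L),
            rng.beta(m.alpha_ord, m.beta_ord, size=L),
        )
        if m.is_binary:
            col = (col >= 0.5).astype(float)
            is_binary[j] = True
        scores[:, j] = col
    return PredictionProfile(labels.id, names, scores, is_binary)


def sim_profiles(
    labels_list: Sequence[DisorderLabels],
    cfg: SimConfig,
    seed: int | None = None,
) -> list[PredictionProfile]:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return [sim_profile(lab, cfg, rng) for lab in labels_list]


def _mask_to_intervals(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """1-based closed intervals of the True runs of a boolean vector."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return ()
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return tuple((int(a) + 1, int(b) + 1) for a, b in zip(starts, ends))


def _draw_raw_score(mode: str, tier: str, rng: np.random.Generator) -> float:
    base = _BASE_OF_MODE[mode]
    lo, hi = TIER_SCORE_BANDS[base][tier]
    if base in _LOG_UNIFORM_METHODS and lo > 0:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def sim_hits(
    labels_list: Sequence[DisorderLabels],
    tier_weights_true: WeightVector,
    cfg: SimConfig,
    seed: int | None = None,
) -> list[list[AlignmentHit]]:
    """Simulated fold-recognition hit lists, one per target.

    Each hit draws a tier from the emission probabilities and is
    *informative* with probability equal to the generative weight of its
    (mode, tier) cell: an informative hit covers the ordered segments
    (plus disordered residues at ``leak_rate``), an uninformative one
    covers a random window. Raw scores are drawn inside the tier band of
    the method, so tier classification recovers the emitted tier exactly.
    """
    if tier_weights_true.kind != "tier24":
        raise InputError("generative weights must be a tier24 vector")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    probs = np.asarray(cfg.tier_emission_probs)
    all_hits = []
    for lab in labels_list:
        L = lab.L
        ordered = lab.states == ORDERED
        target_hits: list[AlignmentHit] = []
        for mode in METHOD_MODES:
            for rank in range(1, cfg.hits_per_mode + 1):
                tier = TIERS[rng.choice(3, p=probs)]
                w_true = float(tier_weights_true.values[tier_index(mode, tier)])
                informative = rng.random() < w_true
                if informative:
                    mask = ordered | (rng.random(L) < cfg.leak_rate)
                else:
                    span = int(rng.integers(min(10, L), L + 1))
                    start = int(rng.integers(0, L - span + 1))
                    mask = np.zeros(L, dtype=bool)
                    mask[start : start + span] = True
                intervals = _mask_to_intervals(mask)
                if not intervals:
                    continue  # nothing aligned (fully disordered target, no leak)
                target_hits.append(
                    AlignmentHit(
                        method_mode=mode,
                        raw_score=_draw_raw_score(mode, tier, rng),
                        intervals=intervals,
                        rank=rank,
                    )
                )
        all_hits.append(target_hits)
    return all_hits


def write_fixture_bundle(
    outdir: str | Path,
    cfg: SimConfig,
    seed: int | None = None,
    tier_weights_true: WeightVector | None = None,
) -> dict:
    """Generate and write a complete fixture bundle to ``outdir``.

    Emits FASTA sequences, a labels TSV, a profile TSV, a hit-table TSV
    and a JSON manifest recording the generative truth. Returns the
    manifest dict.
    """
    from . import io_formats as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    tw = tier_weights_true or default_true_tier_weights()
    pairs = gen_labels(cfg, seed)
    seqs = [s for s, _ in pairs]
    labels = [lab for _, lab in pairs]
    profiles = sim_profiles(labels, cfg, seed + 1)
    hits = sim_hits(labels, tw, cfg, seed + 2)

    io.write_fasta(outdir / "sequences.fasta", seqs)
    io.write_labels(outdir / "labels.tsv", labels)
    io.write_profile_tsv(outdir / "profiles.tsv", profiles)
    io.write_hits_tsv(
        outdir / "hits.tsv",
        {lab.id: h for lab, h in zip(labels, hits)},
    )
    manifest = {
        "format": "idpmeta-fixture v1",
        "seed": int(seed),
        "n_targets": cfg.n_targets,
        "disorder_fraction_target": cfg.disorder_fraction,
        "disorder_fraction_realized": float(
            np.mean(np.concatenate([lab.states for lab in labels]) == DISORDERED)
        ),
        "terminal_enrichment": cfg.terminal_enrichment,
        "leak_rate": cfg.leak_rate,
        "methods": {
            name: {
                "alpha_dis": m.alpha_dis, "beta_dis": m.beta_dis,
                "alpha_ord": m.alpha_ord, "beta_ord": m.beta_ord,
                "is_binary": m.is_binary,
            }
            for name, m in cfg.method_models.items()
        },
        "true_tier_weights": tw.as_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
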