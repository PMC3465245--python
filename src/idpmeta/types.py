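"""Shared domain types for per-residue disorder prediction.

Conventions used throughout the package:

* residue coordinates are 1-based, closed intervals (PDB/CASP style);
* reference labels are two-state (ordered / disordered) with an explicit
  third ``unknown`` state that every metric skips;
* per-residue scores live in [0, 1], with ``NaN`` as the missing-value
  marker for residues a method did not score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ORDERED",
    "DISORDERED",
    "UNKNOWN",
    "STANDARD_AA",
    "IdpmetaError",
    "InputError",
    "SequenceRecord",
    "DisorderLabels",
    "PredictionProfile",
    "AlignmentHit",
    "ConfusionCounts",
    "ClassWeights",
    "WeightVector",
    "validate_pairing",
    "class_weights",
]

# label-state encoding (int8 vectors)
ORDERED = 0
DISORDERED = 1
UNKNOWN = -1

_STATE_CHARS = {"O": ORDERED, "-": ORDERED, "D": DISORDERED, ".": UNKNOWN, "?": UNKNOWN}
_STATE_TO_CHAR = {ORDERED: "O", DISORDERED: "D", UNKNOWN: "."}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

#: default maximum sequence length accepted without warning; kept as a policy
#: (third-party predictors commonly refuse longer chains), not a hard failure.
MAX_SEQUENCE_LENGTH = 1000


class IdpmetaError(Exception):
    """Base class for errors raised by this package."""


class InputError(IdpmetaError):
    """Invalid user-supplied data (maps to CLI exit code 2)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence: identifier plus one-letter residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record requires a non-empty id")
        if not self.residues:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains non-standard residue codes: "
                f"{sorted(bad)} (map ambiguous codes to X first)"
            )
        if len(self.residues) > MAX_SEQUENCE_LENGTH:
            warnings.warn(
                f"sequence {self.id!r} has {len(self.residues)} residues "
                f"(> {MAX_SEQUENCE_LENGTH}); processing anyway",
                stacklevel=2,
            )

    @property
    def L(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DisorderLabels:
    """Per-residue two-state reference with an explicit unknown state.

    ``states`` is an int8 vector over {ORDERED, DISORDERED, UNKNOWN}.
    """

    id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "states", states)
        if states.ndim != 1 or states.size == 0:
            raise InputError(f"labels for {self.id!r} must be a non-empty 1-D vector")
        valid = np.isin(states, (ORDERED, DISORDERED, UNKNOWN))
        if not valid.all():
            raise InputError(f"labels for {self.id!r} contain invalid state codes")

    @classmethod
    def from_string(cls, id: str, text: str) -> "DisorderLabels":
        """Parse a state string over D (disordered), O or - (ordered), . (unknown)."""
        try:
            states = np.array([_STATE_CHARS[c] for c in text.upper()], dtype=np.int8)
        except KeyError as exc:
            raise InputError(f"labels for {id!r}: unknown state symbol {exc.args[0]!r}")
        return cls(id, states)

    def to_string(self) -> str:
        return "".join(_STATE_TO_CHAR[int(s)] for s in self.states)

    @property
    def L(self) -> int:
        return int(self.states.size)

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def known_mask(self) -> np.ndarray:
        return self.states != UNKNOWN

    def counts(self) -> tuple[int, int]:
        """(#ordered, #disordered) over non-unknown residues."""
        return int((self.states == ORDERED).sum()), int((self.states == DISORDERED).sum())


@dataclass
class PredictionProfile:
    """Per-residue score matrix (L x M) for one sequence.

    Columns are named method modes; ``is_binary`` flags columns that carry
    two-state calls (encoded 1.0 = disordered, 0.0 = ordered) rather than
    continuous scores. NaN marks a missing prediction.
    """

    id: str
    methods: list[str]
    scores: np.ndarray
    is_binary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise InputError(f"profile {self.id!r}: scores must be an L x M matrix")
        if len(self.methods) != self.scores.shape[1] or self.scores.shape[1] < 1:
            raise InputError(
                f"profile {self.id!r}: need >= 1 named method column "
                f"({len(self.methods)} names for {self.scores.shape[1]} columns)"
            )
        if len(set(self.methods)) != len(self.methods):
            raise InputError(f"profile {self.id!r}: duplicate method names")
        if self.is_binary is None:
            self.is_binary = np.zeros(len(self.methods), dtype=bool)
        self.is_binary = np.asarray(self.is_binary, dtype=bool)
        if self.is_binary.shape != (len(self.methods),):
            raise InputError(f"profile {self.id!r}: is_binary must have one flag per method")
        finite = self.scores[~np.isnan(self.scores)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise InputError(f"profile {self.id!r}: scores must lie in [0, 1] (or NaN)")

    @property
    def L(self) -> int:
        return int(self.scores.shape[0])

    @property
    def M(self) -> int:
        return int(self.scores.shape[1])

    def column(self, method: str) -> np.ndarray:
        try:
            j = self.methods.index(method)
        except ValueError:
            raise KeyError(f"profile {self.id!r} has no column {method!r}")
        return self.scores[:, j]


@dataclass(frozen=True)
class AlignmentHit:
    """One fold-recognition match against a target sequence.

    ``intervals`` lists the 1-based closed target intervals covered by
    non-gap alignment columns; ``raw_score`` is in the method's native scale
    (e-value, FFAS score, probability, ...).
    """

    method_mode: str
    raw_score: float
    intervals: tuple[tuple[int, int], ...]
    rank: int = 1

    def __post_init__(self) -> None:
        ivs = tuple((int(a), int(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if self.rank < 1:
            raise InputError(f"hit rank must be >= 1, got {self.rank}")
        prev_end = 0
        for a, b in ivs:
            if a < 1 or b < a:
                raise InputError(f"malformed interval {a}-{b} (1-based closed, start <= end)")
            if a <= prev_end:
                raise InputError("hit intervals must be sorted and non-overlapping")
            prev_end = b

    def coverage_mask(self, L: int) -> np.ndarray:
        """Boolean vector of length L, True where the alignment covers the target."""
        mask = np.zeros(L, dtype=bool)
        for a, b in self.intervals:
            if b > L:
                raise InputError(
                    f"hit interval {a}-{b} extends beyond target length {L}"
                )
            mask[a - 1 : b] = True
        return mask


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN at one decision threshold (disordered = positive class)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")


@dataclass(frozen=True)
class ClassWeights:
    """CASP-style class weights: w_disorder is the *ordered* fraction of the
    reference (the reward for catching the rare class) and w_order the
    disordered fraction. They sum to 1."""

    w_disorder: float
    w_order: float

    def __post_init__(self) -> None:
        if self.w_disorder < 0 or self.w_order < 0:
            raise InputError("class weights must be non-negative")
        if abs(self.w_disorder + self.w_order - 1.0) > 1e-9:
            raise InputError("class weights must sum to 1")


WEIGHT_KINDS = {
    "consensus_method_weights": None,  # any length >= 1
    "tier24": 24,
    "tier24_plus_components": 26,
}


@dataclass(frozen=True)
class WeightVector:
    """Named non-negative weights of a declared kind."""

    names: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        if self.kind not in WEIGHT_KINDS:
            raise InputError(f"unknown weight-vector kind {self.kind!r}")
        expected = WEIGHT_KINDS[self.kind]
        if expected is not None and values.size != expected:
            raise InputError(
                f"weight vector of kind {self.kind!r} must have {expected} entries, "
                f"got {values.size}"
            )
        if len(self.names) != values.size:
            raise InputError("weight names and values differ in length")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise InputError("weights must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.values.size)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def validate_pairing(
    seq: SequenceRecord, labels: DisorderLabels, profile: PredictionProfile
) -> tuple[SequenceRecord, DisorderLabels, PredictionProfile]:
    """Check that sequence, labels and profile describe the same target.

    Returns the triple unchanged, or raises :class:`InputError` naming the
    offending id and lengths.
    """
    ids = {seq.id, labels.id, profile.id}
    if len(ids) != 1:
        raise InputError(f"id mismatch between sequence/labels/profile: {sorted(ids)}")
    if not (seq.L == labels.L == profile.L):
        raise InputError(
            f"length mismatch for {seq.id!r}: sequence L={seq.L}, "
            f"labels L={labels.L}, profile L={profile.L}"
        )
    return seq, labels, profile


def class_weights(labels: DisorderLabels | Iterable[DisorderLabels]) -> ClassWeights:
    """Class weights from a reference label set (pooled over the collection).

    w_disorder = fraction of ordered residues; w_order = fraction of
    disordered residues; unknown-state residues are excluded.
    """
    if isinstance(labels, DisorderLabels):
        labels = [labels]
    n_ord = n_dis = 0
    for lab in labels:
        o, d = lab.counts()
        n_ord += o
        n_dis += d
    n = n_ord + n_dis
    if n == 0:
        raise InputError("reference contains no ordered/disordered residues")
    if n_ord == 0 or n_dis == 0:
        raise InputError(
            "reference contains a single class only; class weights (and S_w) undefined"
        )
    return ClassWeights(w_disorder=n_ord / n, w_order=n_dis / n)


def pool_states(labels: Sequence[DisorderLabels]) -> np.ndarray:
    """Concatenate the state vectors of a label collection."""
    return np.concatenate([lab.states for lab in labels])
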