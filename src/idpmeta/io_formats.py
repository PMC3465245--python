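"""Readers and writers for the package's text formats.

Formats handled here: FASTA sequences, two-state label tables, per-residue
score profiles (TSV), fold-recognition hit tables (TSV), PDB-format
REMARK 465 / SEQRES extraction, CASP-style per-residue prediction dumps
(DR lines), the trained-model key-value artifact, and the YAML run
configuration. All coordinates are 1-based; intervals are closed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.SeqUtils import seq1

from .combiner import CombinedModel
from .consensus import ConsensusDisorderPredictor, TerminalCorrection
from .template3d import METHOD_MODES, TIER_WEIGHT_NAMES
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
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "labels_from_remark465",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_hits_tsv",
    "write_hits_tsv",
    "DrRecord",
    "dr_records_from_scores",
    "write_dr",
    "read_dr",
    "save_consensus_model",
    "load_consensus_model",
    "save_combined_model",
    "load_combined_model",
    "load_config",
    "DEFAULT_CONFIG",
]

_AMBIGUOUS = str.maketrans({c: "X" for c in "UBZJ"})
_BINARY_SUFFIX = ":binary"
MODEL_FORMAT_TAG = "idpmeta-model v1"


# ---------------------------------------------------------------- sequences

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read sequences; ids are the first whitespace-delimited header token.

    Sequences are uppercased and the ambiguous codes U/B/Z/J are mapped to
    X with a warning; duplicate ids or other residue codes are errors.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        mapped = seq.translate(_AMBIGUOUS)
        if mapped != seq:
            warnings.warn(f"{rec.id!r}: ambiguous residue codes mapped to X", stacklevel=2)
        records.append(SequenceRecord(rec.id, mapped))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, records: Sequence[SequenceRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.L, width):
                fh.write(rec.residues[i : i + width] + "\n")


# ------------------------------------------------------------------- labels

def read_labels(path: str | Path) -> list[DisorderLabels]:
    """Two-column TSV: id, state string over D / O (or -) / . (unknown)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line == "id\tstates":
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 'id<TAB>states'")
            out.append(DisorderLabels.from_string(parts[0], parts[1]))
    if not out:
        raise InputError(f"no label records found in {path}")
    return out


def write_labels(path: str | Path, labels: Sequence[DisorderLabels]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstates\n")
        for lab in labels:
            fh.write(f"{lab.id}\t{lab.to_string()}\n")


# ------------------------------------------------------- PDB REMARK 465

def labels_from_remark465(
    pdb_text: str,
    chain: str,
    numbering: Sequence[tuple[int, str]] | None = None,
    record_id: str | None = None,
) -> tuple[SequenceRecord, DisorderLabels]:
    """Extract two-state labels from PDB-format text for one chain.

    The chain sequence comes from SEQRES (three-letter codes translated to
    one-letter, non-standard residues to X); residues listed under
    REMARK 465 for that chain become disordered, all others ordered.

    ``numbering`` maps SEQRES positions to author (residue number,
    insertion code) keys; by default positions are numbered sequentially
    1..L with blank insertion codes — with SEQRES-only input there is no
    coordinate record to recover author numbering from. REMARK 465 keys
    with no SEQRES counterpart raise, listing the offenders.
    """
    seqres: list[str] = []
    missing: list[tuple[int, str]] = []
    for line in pdb_text.splitlines():
        if line.startswith("SEQRES"):
            parts = line.split()
            if len(parts) >= 5 and parts[2] == chain:
                seqres.extend(parts[4:])
        elif line.startswith("REMARK 465"):
            parts = line.split()
            rest = parts[2:]
            if len(rest) < 3:
                continue
            # tolerate and drop a leading model-number field
            if len(rest) == 4 and rest[0].isdigit():
                rest = rest[1:]
            if len(rest) != 3:
                continue
            resname, ch, sseq = rest
            if ch != chain or not resname.isalpha() or len(resname) > 3:
                continue
            icode = ""
            if sseq and sseq[-1].isalpha():
                sseq, icode = sseq[:-1], sseq[-1]
            try:
                num = int(sseq)
            except ValueError:
                continue  # header line such as "RES C SSSEQI"
            missing.append((num, icode))
    if not seqres:
        raise InputError(f"no SEQRES records for chain {chain!r}")
    L = len(seqres)
    one = "".join(seq1(r, undef_code="X") for r in seqres).upper().translate(_AMBIGUOUS)
    if numbering is None:
        numbering = [(i, "") for i in range(1, L + 1)]
    if len(numbering) != L:
        raise InputError(f"numbering has {len(numbering)} entries for {L} SEQRES residues")
    key_to_pos = {key: i for i, key in enumerate(numbering)}
    states = np.full(L, ORDERED, dtype=np.int8)
    orphans = [k for k in missing if k not in key_to_pos]
    if orphans:
        raise InputError(
            f"REMARK 465 residues with no SEQRES counterpart in chain {chain!r}: "
            + ", ".join(f"{n}{i}" for n, i in orphans)
        )
    for key in missing:
        states[key_to_pos[key]] = DISORDERED
    rid = record_id or f"chain_{chain}"
    return SequenceRecord(rid, one), DisorderLabels(rid, states)


# ----------------------------------------------------------- profile TSV

def write_profile_tsv(
    path: str | Path,
    profiles: Sequence[PredictionProfile],
    sequences: dict[str, SequenceRecord] | None = None,
) -> None:
    """Multi-target profile table.

    Header: id, index, residue, then one column per method mode; binary
    columns carry a ``:binary`` suffix in the header. Missing scores are
    written as NA; the residue column comes from ``sequences`` when
    provided (X otherwise).
    """
    methods = list(profiles[0].methods)
    header = ["id", "index", "residue"]
    for m, b in zip(methods, profiles[0].is_binary):
        header.append(m + _BINARY_SUFFIX if b else m)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in profiles:
            if list(p.methods) != methods:
                raise InputError("all profiles in one table must share method columns")
            seq = sequences.get(p.id).residues if sequences and p.id in (sequences or {}) else None
            for i in range(p.L):
                row = [p.id, str(i + 1), seq[i] if seq else "X"]
                for v in p.scores[i]:
                    row.append("NA" if math.isnan(v) else f"{v:.6g}")
                fh.write("\t".join(row) + "\n")


def read_profile_tsv(path: str | Path) -> list[PredictionProfile]:
    """Read a multi-target profile table (see :func:`write_profile_tsv`).

    Scores outside [0, 1] by at most 1e-6 are clipped with a warning,
    larger excursions are errors; ragged rows and non-contiguous indices
    are errors with line numbers.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "index", "residue"] or len(header) < 4:
            raise InputError(f"{path}:1: profile header must start id, index, residue, <methods>")
        methods, is_binary = [], []
        for name in header[3:]:
            if name.endswith(_BINARY_SUFFIX):
                methods.append(name[: -len(_BINARY_SUFFIX)])
                is_binary.append(True)
            else:
                methods.append(name)
                is_binary.append(False)
        rows: dict[str, list[list[float]]] = {}
        order: list[str] = []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise InputError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            tid, idx = parts[0], parts[1]
            if tid not in rows:
                rows[tid] = []
                order.append(tid)
            if int(idx) != len(rows[tid]) + 1:
                raise InputError(f"{path}:{lineno}: residue indices must be contiguous from 1")
            vals = []
            for name, tok in zip(methods, parts[3:]):
                if tok in ("NA", "."):
                    vals.append(math.nan)
                    continue
                try:
                    v = float(tok)
                except ValueError:
                    raise InputError(f"{path}:{lineno}: bad score {tok!r} in column {name!r}")
                if v < -1e-6 or v > 1.0 + 1e-6:
                    raise InputError(f"{path}:{lineno}: score {v} outside [0, 1] in column {name!r}")
                if v < 0.0 or v > 1.0:
                    warnings.warn(f"{path}:{lineno}: clipping score {v} to [0, 1]", stacklevel=2)
                    v = min(max(v, 0.0), 1.0)
                vals.append(v)
            rows[tid].append(vals)
    return [
        PredictionProfile(tid, list(methods), np.array(rows[tid]), np.array(is_binary))
        for tid in order
    ]


# -------------------------------------------------------------- hits TSV

_HITS_HEADER = ["target_id", "method_mode", "rank", "raw_score", "intervals"]


def write_hits_tsv(path: str | Path, hits_by_target: dict[str, Sequence[AlignmentHit]]) -> None:
    """Hit table: target_id, method_mode, rank, raw_score, intervals
    (semicolon-separated "start-end", 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HITS_HEADER) + "\n")
        for tid, hits in hits_by_target.items():
            for h in hits:
                ivs = ";".join(f"{a}-{b}" for a, b in h.intervals)
                fh.write(f"{tid}\t{h.method_mode}\t{h.rank}\t{h.raw_score:.6g}\t{ivs}\n")


def read_hits_tsv(path: str | Path) -> dict[str, list[AlignmentHit]]:
    out: dict[str, list[AlignmentHit]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HITS_HEADER:
            raise InputError(f"{path}:1: hit-table header must be {' '.join(_HITS_HEADER)}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise InputError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            tid, mode, rank, raw, ivs = parts
            if mode not in METHOD_MODES:
                raise InputError(f"{path}:{lineno}: unknown method_mode {mode!r}")
            intervals = []
            for chunk in ivs.split(";"):
                try:
                    a, b = chunk.split("-", 1) if not chunk.startswith("-") else (None, None)
                    intervals.append((int(a), int(b)))
                except (ValueError, TypeError):
                    raise InputError(f"{path}:{lineno}: malformed interval {chunk!r}")
            try:
                hit = AlignmentHit(mode, float(raw), tuple(intervals), int(rank))
            except (InputError, ValueError) as exc:
                raise InputError(f"{path}:{lineno}: {exc}")
            out.setdefault(tid, []).append(hit)
    if not out:
        raise InputError(f"no hits found in {path}")
    return out


# ------------------------------------------------------------ DR records

@dataclass(frozen=True)
class DrRecord:
    """One CASP-style per-residue prediction line."""

    residue_index: int
    residue_code: str
    call: str  # D or O
    score: float

    def __post_init__(self) -> None:
        if self.call not in ("D", "O"):
            raise InputError(f"DR call must be D or O, got {self.call!r}")
        if not 0.0 <= self.score <= 1.0:
            raise InputError(f"DR score must lie in [0, 1], got {self.score}")


def dr_records_from_scores(
    residues: str, scores: np.ndarray, threshold: float, strict: bool = False
) -> list[DrRecord]:
    """Per-residue records; the call is consistent with the printed
    (2-decimal) score compared against the threshold."""
    recs = []
    for i, (aa, s) in enumerate(zip(residues, np.asarray(scores, dtype=float)), 1):
        s = 0.0 if math.isnan(s) else round(float(s), 2)
        dis = s > threshold if strict else s >= threshold
        recs.append(DrRecord(i, aa, "D" if dis else "O", s))
    return recs


def write_dr(path: str | Path, records: Sequence[DrRecord]) -> None:
    """Whitespace-separated "index residue call score" lines, 2 decimals."""
    with open(path, "w") as fh:
        for i, r in enumerate(records, 1):
            if r.residue_index != i:
                raise InputError("DR residue indices must be contiguous from 1")
            fh.write(f"{r.residue_index} {r.residue_code} {r.call} {r.score:.2f}\n")


def read_dr(path: str | Path) -> list[DrRecord]:
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise InputError(f"{path}:{lineno}: expected 'index residue call score'")
            recs.append(DrRecord(int(parts[0]), parts[1], parts[2], float(parts[3])))
    return recs


# -------------------------------------------------------- model artifacts

def _write_kv(path: str | Path, items: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for k, v in items:
            fh.write(f"{k}: {v}\n")


def _read_kv(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if ": " not in line:
                raise InputError(f"{path}:{lineno}: expected 'key: value'")
            k, v = line.split(": ", 1)
            out[k] = v
    if out.get("format") != MODEL_FORMAT_TAG:
        raise InputError(f"{path}: missing or unsupported model format tag")
    return out


def save_consensus_model(path: str | Path, est: ConsensusDisorderPredictor) -> None:
    """Serialize a fitted consensus predictor as a key-value text artifact."""
    items = [
        ("format", MODEL_FORMAT_TAG),
        ("kind", "consensus"),
        ("mode", est.mode),
        ("threshold", f"{est.threshold_:.17g}"),
        ("binary_negative", f"{est.binary_negative:.17g}"),
    ]
    for name, w in est.method_weights_.as_dict().items():
        items.append((f"weight.{name}", f"{w:.17g}"))
    tc = est.terminal_correction_
    for i in range(tc.n_proximal):
        items.append((f"nterm.{i + 1}", f"{tc.factors_nterm[i]:.17g}"))
    for i in range(tc.n_proximal):
        items.append((f"cterm.{i + 1}", f"{tc.factors_cterm[i]:.17g}"))
    _write_kv(path, items)


def load_consensus_model(path: str | Path) -> ConsensusDisorderPredictor:
    kv = _read_kv(path)
    if kv.get("kind") != "consensus":
        raise InputError(f"{path}: not a consensus model artifact")
    est = ConsensusDisorderPredictor(
        mode=kv["mode"], binary_negative=float(kv["binary_negative"])
    )
    names = [k[len("weight."):] for k in kv if k.startswith("weight.")]
    est.method_weights_ = WeightVector(
        tuple(names),
        np.array([float(kv[f"weight.{n}"]) for n in names]),
        "consensus_method_weights",
    )
    n = max(int(k.split(".")[1]) for k in kv if k.startswith("nterm."))
    est.terminal_correction_ = TerminalCorrection(
        np.array([float(kv[f"nterm.{i + 1}"]) for i in range(n)]),
        np.array([float(kv[f"cterm.{i + 1}"]) for i in range(n)]),
        n_proximal=n,
    )
    est.threshold_ = float(kv["threshold"])
    return est


def save_combined_model(path: str | Path, model: CombinedModel) -> None:
    """Serialize a combined model: 24 tier weights + 2 component weights."""
    items = [
        ("format", MODEL_FORMAT_TAG),
        ("kind", "combined"),
        ("fitness_kind", model.fitness_kind),
        ("threshold", f"{model.threshold:.17g}"),
        ("component.consensus", f"{model.component_weights[0]:.17g}"),
        ("component.template", f"{model.component_weights[1]:.17g}"),
    ]
    for name, w in model.tier_weights.as_dict().items():
        items.append((f"tier.{name}", f"{w:.17g}"))
    _write_kv(path, items)


def load_combined_model(path: str | Path) -> CombinedModel:
    kv = _read_kv(path)
    if kv.get("kind") != "combined":
        raise InputError(f"{path}: not a combined model artifact")
    tier = WeightVector(
        TIER_WEIGHT_NAMES,
        np.array([float(kv[f"tier.{n}"]) for n in TIER_WEIGHT_NAMES]),
        "tier24",
    )
    return CombinedModel(
        tier_weights=tier,
        component_weights=(float(kv["component.consensus"]), float(kv["component.template"])),
        threshold=float(kv["threshold"]),
        fitness_kind=kv["fitness_kind"],
    )


# ---------------------------------------------------------------- config

#: flat YAML configuration schema: key -> (type, default)
DEFAULT_CONFIG: dict[str, tuple[type, object]] = {
    "seed": (int, 0),
    "mode": (str, "continuous"),
    "fitness": (str, "sw"),
    "min_weight": (float, 0.0),
    "use_terminal_correction": (bool, True),
    "max_hits": (int, 10),
    "no_hit_score": (float, 1.0),
    "ga_population": (int, 80),
    "ga_generations": (int, 100),
    "ga_crossover_prob": (float, 0.9),
    "ga_mutation_prob": (float, 0.02),
    "ga_mutation_sigma": (float, 0.1),
    "n_targets": (int, 50),
    "disorder_fraction": (float, 0.2345),
    "terminal_enrichment": (float, 2.0),
    "leak_rate": (float, 0.05),
}


def load_config(path: str | Path | None) -> dict:
    """Load a flat YAML config, validate against the schema, merge defaults."""
    cfg = {k: default for k, (_, default) in DEFAULT_CONFIG.items()}
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a flat YAML mapping")
    for key, value in data.items():
        if key not in DEFAULT_CONFIG:
            raise InputError(f"{path}: unknown config key {key!r}")
        typ, _ = DEFAULT_CONFIG[key]
        if typ is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if not isinstance(value, typ) or (typ is int and isinstance(value, bool)):
            raise InputError(f"{path}: config key {key!r} must be {typ.__name__}")
        cfg[key] = value
    return cfg
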