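"""Sequence datasets, background models and synthetic CRE construction.

This module holds the data layer of pymocca: class-labelled DNA sequences,
FASTA input/output, N-th order Markov background models, and the synthetic
planted-motif generator used to emulate the classic CRE training-set design
(positives with clustered motif co-occurrences, "dummy-CRE" negatives with
the same motif counts but randomised placement, and pure-background
"dummy genomic" negatives).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from numpy.lib.stride_tricks import sliding_window_view

ALPHABET = "ACGT"
_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DEGENERATE = set("RYSWKMBDHV")
_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "LabelledSequence",
    "MarkovModel",
    "PlantingPlan",
    "FastaParseError",
    "PlantingError",
    "read_fasta",
    "write_fasta",
    "train_markov",
    "generate_sequences",
    "make_planted_cre_set",
    "randomize_motif_placement",
    "reverse_complement",
    "encode",
    "decode",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


class PlantingError(ValueError):
    """Raised when a planting plan cannot be realised within a sequence."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T/N string to integer codes 0..4 (N = 4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in zip("ACGT", range(4)):
        out[arr == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Upper-case and restrict to {A,C,G,T,N}.

    Degenerate IUPAC letters are conservatively collapsed to N (with a
    warning); anything else is an error.
    """
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    out = []
    n_mapped = 0
    for ch in s:
        if ch in _VALID:
            out.append(ch)
        elif ch in _DEGENERATE:
            out.append("N")
            n_mapped += 1
        else:
            raise ValueError(f"invalid nucleotide {ch!r} in {context}")
    warnings.warn(
        f"{n_mapped} degenerate IUPAC letter(s) in {context} mapped to N",
        stacklevel=3,
    )
    return "".join(out)


@dataclass
class LabelledSequence:
    """A DNA sequence with an identifier, a class label and a weight."""

    id: str
    seq: str
    label: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq, context=f"sequence {self.id!r}")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, id_suffix: str = "_rc") -> "LabelledSequence":
        return LabelledSequence(
            self.id + id_suffix, reverse_complement(self.seq), self.label, self.weight
        )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path, label: str = "") -> list[LabelledSequence]:
    """Read a FASTA file into labelled sequences.

    The header token before the first whitespace becomes the id; sequences are
    case-folded to upper case. Duplicate ids and sequence data preceding the
    first header are errors.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(LabelledSequence(rec.id, str(rec.seq), label))
    return records


def write_fasta(seqs: Iterable[LabelledSequence], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Markov background models


@dataclass
class MarkovModel:
    """An N-th order Markov chain over {A,C,G,T}.

    ``transitions`` has one row per length-N context (base-4 encoded, most
    significant digit first) giving the conditional distribution of the next
    nucleotide; ``initial`` is a distribution over starting contexts. Order 0
    degenerates to an i.i.d. nucleotide model (a single context row).
    """

    order: int
    transitions: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        n_ctx = 4**self.order
        if self.transitions.shape != (n_ctx, 4):
            raise ValueError(f"transitions must have shape ({n_ctx}, 4)")
        if self.initial.shape != (n_ctx,):
            raise ValueError(f"initial must have shape ({n_ctx},)")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each conditional distribution must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @classmethod
    def uniform(cls, order: int = 0) -> "MarkovModel":
        n_ctx = 4**order
        return cls(order, np.full((n_ctx, 4), 0.25), np.full(n_ctx, 1.0 / n_ctx))

    @classmethod
    def iid(cls, probs: Sequence[float]) -> "MarkovModel":
        p = np.asarray(probs, dtype=float)
        return cls(0, p[None, :], np.array([1.0]))


def train_markov(seqs: Iterable[LabelledSequence | str], order: int) -> MarkovModel:
    """Fit an order-N Markov chain by add-one-smoothed relative frequencies.

    Windows containing N are skipped. The initial-context distribution is the
    (also smoothed) empirical frequency of N-mers over all positions.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    k = order
    n_ctx = 4**k
    counts = np.zeros((n_ctx, 4), dtype=np.int64)
    init_counts = np.zeros(n_ctx, dtype=np.int64)
    pow4 = 4 ** np.arange(k - 1, -1, -1) if k else np.zeros(0, dtype=int)
    for s in seqs:
        seq = s.seq if isinstance(s, LabelledSequence) else str(s)
        codes = encode(seq)
        if len(codes) < k + 1:
            continue
        win = sliding_window_view(codes, k + 1)
        valid = (win < 4).all(axis=1)
        if k:
            ctx = win[valid, :k].astype(np.int64) @ pow4
        else:
            ctx = np.zeros(valid.sum(), dtype=np.int64)
        np.add.at(counts, (ctx, win[valid, k].astype(np.int64)), 1)
        if k:
            cwin = sliding_window_view(codes, k)
            cvalid = (cwin < 4).all(axis=1)
            np.add.at(init_counts, cwin[cvalid].astype(np.int64) @ pow4, 1)
    if counts.sum() == 0:
        raise ValueError("no usable (N-free) sequence windows to train on")
    transitions = (counts + 1) / (counts.sum(axis=1, keepdims=True) + 4)
    if k:
        initial = (init_counts + 1) / (init_counts.sum() + n_ctx)
    else:
        initial = np.array([1.0])
    return MarkovModel(order, transitions, initial)


def _generate_codes(model: MarkovModel, length: int, rng: np.random.Generator) -> np.ndarray:
    k = model.order
    if k == 0:
        return rng.choice(4, size=length, p=model.transitions[0])
    ctx = int(rng.choice(len(model.initial), p=model.initial))
    prefix = np.zeros(k, dtype=np.int64)
    c = ctx
    for j in range(k - 1, -1, -1):
        prefix[j] = c % 4
        c //= 4
    codes = np.empty(length, dtype=np.int64)
    codes[: min(k, length)] = prefix[:length]
    if length <= k:
        return codes
    cum = model.transitions.cumsum(axis=1)
    r = rng.random(length - k)
    mod = 4**k
    for i in range(k, length):
        b = int(np.searchsorted(cum[ctx], r[i - k], side="right"))
        b = min(b, 3)
        codes[i] = b
        ctx = (ctx * 4 + b) % mod
    return codes


def generate_sequences(
    model: MarkovModel,
    count: int,
    length: int,
    seed: int,
    label: str = "",
    id_prefix: str = "bg",
) -> list[LabelledSequence]:
    """Sample ``count`` sequences of ``length`` bp from a Markov model.

    Deterministic given ``seed``.
    """
    if count <= 0 or length <= 0:
        raise ValueError("count and length must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(count):
        codes = _generate_codes(model, length, rng)
        out.append(LabelledSequence(f"{id_prefix}{i}", decode(codes), label))
    return out


# ---------------------------------------------------------------------------
# Planted-motif synthetic CRE sets


@dataclass(frozen=True)
class PlantingPlan:
    """How to plant motif instances into a background sequence.

    ``counts`` maps motif name to the number of instances per sequence.
    ``placement`` is "clustered" (all instances fall within a randomly
    positioned window of ``cluster_width`` bp, emulating the dense local motif
    neighbourhoods of real CREs) or "uniform" (instances are scattered
    independently over the whole sequence, preserving marginal counts while
    destroying clustering — the "dummy-CRE" construction).
    """

    counts: Mapping[str, int]
    placement: str = "clustered"
    cluster_width: int = 500

    def __post_init__(self) -> None:
        if self.placement not in ("clustered", "uniform"):
            raise ValueError("placement must be 'clustered' or 'uniform'")


def _place_instances(
    rng: np.random.Generator, sizes: list[int], lo: int, hi: int, tries: int = 200
) -> list[int]:
    """Sample non-overlapping start positions for instances of given sizes."""
    if sum(sizes) > hi - lo:
        raise PlantingError("infeasible plan: motif instances exceed available span")
    for _ in range(tries):
        starts = [int(rng.integers(lo, hi - size + 1)) for size in sizes]
        ivs = sorted(zip(starts, sizes))
        if all(ivs[i][0] + ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1)):
            return starts
    raise PlantingError("infeasible plan: could not place motif instances without overlap")


def _plant(
    rng: np.random.Generator,
    background: MarkovModel,
    motifs_by_name: Mapping[str, object],
    plan: PlantingPlan | None,
    length: int,
) -> tuple[str, list[tuple[str, int, int, str]]]:
    codes = _generate_codes(background, length, rng)
    seq = list(decode(codes))
    truth: list[tuple[str, int, int, str]] = []
    if plan is None or not plan.counts:
        return "".join(seq), truth
    names, sizes = [], []
    for name, n in plan.counts.items():
        motif = motifs_by_name[name]
        for _ in range(int(n)):
            names.append(name)
            sizes.append(len(motif))
    if not names:
        return "".join(seq), truth
    if plan.placement == "clustered":
        cw = min(plan.cluster_width, length)
        lo = int(rng.integers(0, length - cw + 1))
        hi = lo + cw
    else:
        lo, hi = 0, length
    starts = _place_instances(rng, sizes, lo, hi)
    for name, start in zip(names, starts):
        motif = motifs_by_name[name]
        instance = motif.sample_instance(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = instance if strand == "+" else reverse_complement(instance)
        seq[start : start + len(planted)] = planted
        truth.append((name, start, start + len(planted), strand))
    truth.sort(key=lambda t: t[1])
    return "".join(seq), truth


def make_planted_cre_set(
    background: MarkovModel,
    motifs: Sequence[object],
    plans: Mapping[str, PlantingPlan | None],
    count: int | Mapping[str, int],
    length: int,
    seed: int,
) -> tuple[list[LabelledSequence], dict[str, list[tuple[str, int, int, str]]]]:
    """Generate a class-labelled synthetic CRE dataset with ground truth.

    ``plans`` maps class label to a PlantingPlan (or None for pure
    background). Returns the sequences and, per sequence id, the list of
    planted (motif, start, end, strand) instances.
    """
    rng = np.random.default_rng(seed)
    motifs_by_name = {m.name: m for m in motifs}
    seqs: list[LabelledSequence] = []
    truth: dict[str, list[tuple[str, int, int, str]]] = {}
    for label, plan in plans.items():
        n = count[label] if isinstance(count, Mapping) else count
        for i in range(n):
            seq, planted = _plant(rng, background, motifs_by_name, plan, length)
            sid = f"{label}_{i}"
            seqs.append(LabelledSequence(sid, seq, label))
            truth[sid] = planted
    return seqs, truth


def randomize_motif_placement(
    positives: Sequence[LabelledSequence],
    occurrences: Mapping[str, Sequence[object]],
    motifs: Sequence[object],
    background: MarkovModel,
    seed: int,
    label: str = "dummy-cre",
) -> list[LabelledSequence]:
    """Build dummy-CRE negatives matching per-sequence motif counts.

    For each positive, a background sequence of the same length is generated
    and the positive's per-motif occurrence counts are re-planted at
    independently uniform positions, preserving motif frequency while
    destroying clustering and pairing. If the raw counts (which may include
    overlapping occurrences) cannot be placed without overlap, counts are
    decremented until placement succeeds.
    """
    rng = np.random.default_rng(seed)
    motifs_by_name = {m.name: m for m in motifs}
    out = []
    for i, pos in enumerate(positives):
        counts: dict[str, int] = {}
        for occ in occurrences.get(pos.id, ()):
            counts[occ.motif] = counts.get(occ.motif, 0) + 1
        while True:
            plan = PlantingPlan({k: v for k, v in counts.items() if v > 0}, "uniform")
            try:
                seq, _ = _plant(rng, background, motifs_by_name, plan, len(pos))
                break
            except PlantingError:
                busiest = max(counts, key=counts.get)
                counts[busiest] -= 1
                if all(v <= 0 for v in counts.values()):
                    seq, _ = _plant(rng, background, motifs_by_name, None, len(pos))
                    break
        out.append(LabelledSequence(f"{label}_{i}", seq, label))
    return out
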