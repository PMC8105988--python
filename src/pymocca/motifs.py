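"""Motif representations, the parallel IUPAC FSM scanner, PWM scanning and
PWM threshold calibration.

Two motif types are supported: degenerate IUPAC-code motifs (with an optional
Hamming mismatch budget) and position weight matrices (PWMs) in the
FlyFactorSurvey horizontal PSSM text format. All IUPAC motifs are compiled
into a single deterministic finite state machine that reports occurrences of
every motif, on both strands, in one pass over the sequence.

Coordinates are 0-based half-open throughout; BED conversion happens at the
output boundary. A sequence position holding N never matches any motif
position — a window containing N cannot match even when mismatch budget
remains.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqdata import LabelledSequence, MarkovModel, encode

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# per IUPAC letter, the set of base codes (0..3) it matches
_CODE_SETS = {
    letter: frozenset("ACGT".index(b) for b in bases)
    for letter, bases in IUPAC_CODES.items()
}

__all__ = [
    "IupacMotif",
    "PwmMotif",
    "MotifOccurrence",
    "MotifScannerFsm",
    "MotifScanner",
    "parse_motif_xml",
    "parse_pssm_file",
    "build_fsm",
    "scan_iupac",
    "scan_pwm",
    "calibrate_pwm_threshold",
    "occurrences_to_bed",
    "reverse_complement_iupac",
]


def reverse_complement_iupac(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IupacMotif:
    """A named degenerate-IUPAC motif with an optional mismatch budget."""

    name: str
    pattern: str
    mismatches: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        if len(self.pattern) < 1:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        for i, ch in enumerate(self.pattern):
            if ch not in IUPAC_CODES:
                raise ValueError(
                    f"motif {self.name!r}: invalid IUPAC code {ch!r} at position {i}"
                )
        if not 0 <= self.mismatches <= 2:
            raise ValueError(
                f"motif {self.name!r}: mismatch budget must be between 0 and 2"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    def sample_instance(self, rng: np.random.Generator) -> str:
        """Draw a concrete A/C/G/T realisation of the pattern."""
        return "".join(
            sorted(IUPAC_CODES[ch])[rng.integers(len(IUPAC_CODES[ch]))]
            for ch in self.pattern
        )


@dataclass
class PwmMotif:
    """A position weight matrix motif (log-odds scores, rows A,C,G,T)."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None
    probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError(f"PWM {self.name!r}: matrix must be 4 x L with L >= 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"PWM {self.name!r}: background must sum to 1")
        if not np.all(np.isfinite(self.matrix.max(axis=0))):
            raise ValueError(f"PWM {self.name!r}: non-finite column maximum")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts,
        background: Sequence[float] | None = None,
        pseudocount: float = 1.0,
    ) -> "PwmMotif":
        """Build a log-odds PWM from a 4 x L count (or frequency) matrix.

        Counts are pseudocount-smoothed, column-normalised to probabilities
        p[b][i], then transformed to w[b][i] = ln(p[b][i] / background[b]).
        """
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"PWM {name!r}: negative matrix entries")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        return cls(name, np.log(probs / bg[:, None]), bg, None, probs)

    def __len__(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=0).sum())

    def rc_matrix(self) -> np.ndarray:
        """The matrix scoring the reverse strand in forward coordinates."""
        return self.matrix[::-1, ::-1]

    def sample_instance(self, rng: np.random.Generator) -> str:
        if self.probs is not None:
            probs = self.probs
        else:  # recover probabilities from the log-odds transform
            probs = np.exp(self.matrix) * self.background[:, None]
            probs = probs / probs.sum(axis=0)
        return "".join(
            "ACGT"[rng.choice(4, p=probs[:, i])] for i in range(probs.shape[1])
        )


@dataclass(frozen=True, order=True)
class MotifOccurrence:
    """A motif match in 0-based half-open coordinates."""

    seq_id: str = field(compare=False)
    motif: str
    start: int
    end: int
    strand: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


# ---------------------------------------------------------------------------
# Motif file parsing


def parse_motif_xml(path) -> list[IupacMotif]:
    """Parse IUPAC motifs from an XML file.

    Schema: a root element containing ``<motif name="..." iupac="..."
    [mismatches="k"]/>`` elements (the pattern may alternatively be given as
    element text). Names must be unique.
    """
    tree = ET.parse(str(path))
    motifs: list[IupacMotif] = []
    seen: set[str] = set()
    for el in tree.getroot().iter("motif"):
        name = el.get("name")
        if not name:
            raise ValueError(f"{path}: motif element without a name")
        pattern = el.get("iupac") or (el.text or "").strip()
        mismatches = int(el.get("mismatches", "0"))
        if name in seen:
            raise ValueError(f"{path}: duplicate motif name {name!r}")
        seen.add(name)
        motifs.append(IupacMotif(name, pattern, mismatches))
    return motifs


def parse_pssm_file(
    path, background: Sequence[float] | None = None, pseudocount: float = 1.0
) -> list[PwmMotif]:
    """Parse FlyFactorSurvey-style horizontal PSSM records.

    Each record is a ``>name`` header followed by four rows labelled A, C, G
    and T (an optional ``|`` separator after the label is tolerated) holding
    equal numbers of counts or frequencies. Thresholds are left unset.
    """
    rows_order = "ACGT"
    motifs: list[PwmMotif] = []
    name = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal name, rows
        if name is None:
            return
        missing = [b for b in rows_order if b not in rows]
        if missing:
            raise ValueError(f"{path}: PSSM {name!r} missing row(s) {missing}")
        lengths = {len(rows[b]) for b in rows_order}
        if len(lengths) != 1:
            raise ValueError(f"{path}: PSSM {name!r} has rows of unequal length")
        counts = np.array([rows[b] for b in rows_order], dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"{path}: PSSM {name!r} has negative entries")
        motifs.append(PwmMotif.from_counts(name, counts, background, pseudocount))
        name, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                continue
            fields = line.replace("|", " ").split()
            if name is None or fields[0].upper() not in rows_order:
                continue
            rows[fields[0].upper()] = [float(x) for x in fields[1:]]
    flush()
    return motifs


# ---------------------------------------------------------------------------
# The parallel IUPAC finite state machine


class MotifScannerFsm:
    """A lazily built DFA matching all IUPAC motifs (both strands) at once.

    States are sets of partial-match items (pattern, position, mismatches
    used), determinised by subset construction on demand and memoised, so
    scanning is a single pass with one table lookup per base regardless of the
    number of motifs. Reverse-strand matching is achieved by also compiling
    the reverse-complemented pattern of each motif; a motif equal to its own
    reverse complement is compiled once and reported on the '+' strand only.
    """

    def __init__(self, motifs: Sequence[IupacMotif]):
        if not motifs:
            raise ValueError("at least one motif is required")
        self.motifs = list(motifs)
        # entries: (motif index, pattern as tuple of base-code sets, strand)
        self._entries: list[tuple[int, tuple[frozenset[int], ...], str]] = []
        for mi, m in enumerate(self.motifs):
            self._entries.append(
                (mi, tuple(_CODE_SETS[ch] for ch in m.pattern), "+")
            )
            rc = reverse_complement_iupac(m.pattern)
            if rc != m.pattern:
                self._entries.append(
                    (mi, tuple(_CODE_SETS[ch] for ch in rc), "-")
                )
        self._budgets = [self.motifs[e[0]].mismatches for e in self._entries]
        self._state_index: dict[frozenset, int] = {frozenset(): 0}
        self._state_items: list[frozenset] = [frozenset()]
        # per state: 5 successor slots (A,C,G,T,N) and matching emission tuples
        self._next: list[list[int | None]] = [[None] * 5]
        self._emit: list[list[tuple[tuple[int, int], ...] | None]] = [[None] * 5]

    def _step_tables(self, state: int, c: int) -> tuple[int, tuple[tuple[int, int], ...]]:
        if c == 4:  # N: no motif position matches, all partial matches die
            self._next[state][4] = 0
            self._emit[state][4] = ()
            return 0, ()
        best: dict[tuple[int, int], int] = {}  # (entry, pos) -> min mismatches

        def add(eidx: int, pos: int, mm: int) -> None:
            key = (eidx, pos)
            if key not in best or mm < best[key]:
                best[key] = mm

        for eidx, pos, mm in self._state_items[state]:
            pattern = self._entries[eidx][1]
            if c in pattern[pos]:
                add(eidx, pos + 1, mm)
            elif mm < self._budgets[eidx]:
                add(eidx, pos + 1, mm + 1)
        for eidx, (_, pattern, _) in enumerate(self._entries):
            if c in pattern[0]:
                add(eidx, 1, 0)
            elif self._budgets[eidx] > 0:
                add(eidx, 1, 1)
        emits: dict[int, int] = {}
        items = []
        for (eidx, pos), mm in best.items():
            if pos == len(self._entries[eidx][1]):
                if eidx not in emits or mm < emits[eidx]:
                    emits[eidx] = mm
            else:
                items.append((eidx, pos, mm))
        key = frozenset(items)
        nxt = self._state_index.get(key)
        if nxt is None:
            nxt = len(self._state_items)
            self._state_index[key] = nxt
            self._state_items.append(key)
            self._next.append([None] * 5)
            self._emit.append([None] * 5)
        emit = tuple(
            (eidx, len(self._entries[eidx][1])) for eidx in sorted(emits)
        )
        self._next[state][c] = nxt
        self._emit[state][c] = emit
        return nxt, emit

    def scan(
        self, seq: LabelledSequence | str, both_strands: bool = True
    ) -> list[MotifOccurrence]:
        if isinstance(seq, LabelledSequence):
            sid, s = seq.id, seq.seq
        else:
            sid, s = "", str(seq)
        codes = encode(s)
        occs: list[MotifOccurrence] = []
        nxt_tab, emit_tab = self._next, self._emit
        state = 0
        for i in range(len(codes)):
            c = int(codes[i])
            nxt = nxt_tab[state][c]
            if nxt is None:
                nxt, emit = self._step_tables(state, c)
            else:
                emit = emit_tab[state][c]
            if emit:
                for eidx, plen in emit:
                    mi, _, strand = self._entries[eidx]
                    if strand == "-" and not both_strands:
                        continue
                    occs.append(
                        MotifOccurrence(
                            sid, self.motifs[mi].name, i + 1 - plen, i + 1, strand, 1.0
                        )
                    )
            state = nxt
        occs.sort(key=lambda o: (o.start, o.motif, o.strand))
        return occs


def build_fsm(motifs: Sequence[IupacMotif]) -> MotifScannerFsm:
    return MotifScannerFsm(motifs)


def scan_iupac(
    fsm: MotifScannerFsm, seq: LabelledSequence | str, both_strands: bool = True
) -> list[MotifOccurrence]:
    return fsm.scan(seq, both_strands=both_strands)


# ---------------------------------------------------------------------------
# PWM scanning and threshold calibration


def _pwm_window_scores(matrix: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score all offsets of a 4 x L matrix; windows containing N get -inf."""
    L = matrix.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    safe = np.where(codes < 4, codes, 0)
    scores = np.zeros(n)
    for j in range(L):
        scores += matrix[safe[j : j + n], j]
    has_n = codes == 4
    if has_n.any():
        bad = np.convolve(has_n.astype(int), np.ones(L, dtype=int), mode="valid") > 0
        scores[bad] = -np.inf
    return scores


def scan_pwm(
    motif: PwmMotif, seq: LabelledSequence | str, both_strands: bool = True
) -> list[MotifOccurrence]:
    """Report every offset (each strand) scoring at least the threshold."""
    if motif.threshold is None:
        raise ValueError(f"PWM {motif.name!r}: threshold is unset")
    if isinstance(seq, LabelledSequence):
        sid, s = seq.id, seq.seq
    else:
        sid, s = "", str(seq)
    codes = encode(s)
    L = len(motif)
    occs: list[MotifOccurrence] = []
    strands = [("+", motif.matrix)]
    if both_strands:
        strands.append(("-", motif.rc_matrix()))
    for strand, matrix in strands:
        scores = _pwm_window_scores(matrix, codes)
        for i in np.flatnonzero(scores >= motif.threshold):
            occs.append(
                MotifOccurrence(sid, motif.name, int(i), int(i) + L, strand, float(scores[i]))
            )
    occs.sort(key=lambda o: (o.start, o.motif, o.strand))
    return occs


def calibrate_pwm_threshold(
    motif: PwmMotif,
    background: MarkovModel | Sequence[float] | None = None,
    target_rate: float = 1.0,
    total_length: int = 1_000_000,
    seed: int = 0,
    both_strands: bool = True,
) -> float:
    """Set the PWM score cutoff for an expected occurrence rate per kilobase.

    An i.i.d. background of ``total_length`` bp is simulated, all windows on
    both strands are scored, and the threshold is set to the empirical score
    quantile at which round(target_rate * total_length / 1000) windows score
    at or above it. The returned threshold is also stored on the motif.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if background is None:
        probs = np.full(4, 0.25)
    elif isinstance(background, MarkovModel):
        if background.order != 0:
            raise ValueError("calibration background must be an order-0 (i.i.d.) model")
        probs = background.transitions[0]
    else:
        probs = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=total_length, p=probs)
    scores = _pwm_window_scores(motif.matrix, codes)
    if both_strands:
        scores = np.concatenate([scores, _pwm_window_scores(motif.rc_matrix(), codes)])
    k = int(round(target_rate * total_length / 1000.0))
    if k < 1:
        raise ValueError("target rate yields fewer than one occurrence; increase length")
    if k > len(scores):
        raise ValueError(
            f"target rate implies {k} occurrences but only {len(scores)} windows exist"
        )
    s_k = float(np.partition(scores, len(scores) - k)[len(scores) - k])
    # discrete PWM score distributions produce tie blocks at the quantile;
    # choose the side of the block whose count is closer to the target
    count_ge = int((scores >= s_k).sum())
    count_gt = int((scores > s_k).sum())
    if count_gt > 0 and abs(count_gt - k) < abs(count_ge - k):
        threshold = float(scores[scores > s_k].min())
    else:
        threshold = s_k
    motif.threshold = threshold
    return threshold


# ---------------------------------------------------------------------------
# Unified scanning and BED export


class MotifScanner:
    """Scans sequences for a mixed set of IUPAC and PWM motifs."""

    def __init__(self, motifs: Sequence[IupacMotif | PwmMotif], both_strands: bool = True):
        self.motifs = list(motifs)
        self.both_strands = both_strands
        iupac = [m for m in self.motifs if isinstance(m, IupacMotif)]
        self.pwms = [m for m in self.motifs if isinstance(m, PwmMotif)]
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("motif names must be unique")
        self.fsm = MotifScannerFsm(iupac) if iupac else None

    @property
    def motif_names(self) -> list[str]:
        return sorted(m.name for m in self.motifs)

    def scan(self, seq: LabelledSequence | str) -> list[MotifOccurrence]:
        occs: list[MotifOccurrence] = []
        if self.fsm is not None:
            occs.extend(self.fsm.scan(seq, both_strands=self.both_strands))
        for pwm in self.pwms:
            occs.extend(scan_pwm(pwm, seq, both_strands=self.both_strands))
        occs.sort(key=lambda o: (o.start, o.motif, o.strand))
        return occs


def occurrences_to_bed(occs: Iterable[MotifOccurrence], path) -> None:
    """Write occurrences as BED6 (score = PWM score x 100, clamped 0-1000)."""
    with open(path, "w") as fh:
        for o in occs:
            score = int(min(1000, max(0, round(o.score * 100))))
            fh.write(f"{o.seq_id}\t{o.start}\t{o.end}\t{o.motif}\t{score}\t{o.strand}\n")
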