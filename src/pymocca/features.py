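"""Feature-space formulations turning sequence windows plus motif
occurrences into named feature vectors.

Supported spaces: per-motif occurrence frequencies, unordered motif-pair
occurrence frequencies within a distance cutoff, distance-binned pair
frequencies, dinucleotide frequencies, GC content and k-mer spectra.
Feature vectors are pandas Series with deterministic, sorted name order;
matrices over many sequences are DataFrames.

Conventions (fixed so that window-boundary behaviour is testable): an
occurrence belongs to a window iff its start coordinate lies in the window;
pair distances are measured centre-to-centre; frequency spaces default to
per-kilobase normalisation so that windows of different lengths are
comparable.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement, product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .motifs import MotifOccurrence, MotifScanner
from .seqdata import LabelledSequence, encode

KINDS = (
    "motif-frequency",
    "motif-pair-frequency",
    "motif-pair-distance-binned",
    "dinucleotide-frequency",
    "gc-content",
    "kmer-spectrum",
)

__all__ = [
    "FeatureSpace",
    "SequenceFeaturizer",
    "motif_frequencies",
    "motif_pair_frequencies",
    "pair_distance_binned",
    "dinucleotide_frequencies",
    "gc_content",
    "kmer_spectrum",
    "pair_name",
]


@dataclass(frozen=True)
class FeatureSpace:
    """Specification of one feature space and its parameters."""

    kind: str
    pair_cutoff: int = 219  # bp, centre-to-centre; the classic PREdictor window
    bin_width: int = 100
    k: int = 4
    normalization: str = "per-kb"  # {"per-kb", "per-window", "raw"}

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature space kind {self.kind!r}")
        if self.pair_cutoff <= 0:
            raise ValueError("pair distance cutoff must be positive")
        if not 1 <= self.k <= 8:
            raise ValueError("k must be in [1, 8]")
        if self.normalization not in ("per-kb", "per-window", "raw"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def _normalize(values: pd.Series, window_len: int, normalization: str) -> pd.Series:
    if normalization == "per-kb":
        return values / (window_len / 1000.0)
    if normalization == "per-window":
        return values / float(window_len)
    return values


def pair_name(m1: str, m2: str) -> str:
    a, b = sorted((m1, m2))
    return f"{a}::{b}"


def motif_frequencies(
    occs: Iterable[MotifOccurrence],
    window: tuple[int, int],
    motif_names: Sequence[str],
    normalization: str = "per-kb",
) -> pd.Series:
    """Per-motif occurrence counts within a window (both strands summed)."""
    names = sorted(motif_names)
    counts = pd.Series(0.0, index=names)
    lo, hi = window
    for o in occs:
        if lo <= o.start < hi and o.motif in counts.index:
            counts[o.motif] += 1
    return _normalize(counts, hi - lo, normalization)


def motif_pair_frequencies(
    occs: Iterable[MotifOccurrence],
    window: tuple[int, int],
    motif_names: Sequence[str],
    cutoff: int = 219,
    normalization: str = "per-kb",
) -> pd.Series:
    """Unordered motif-pair counts within a centre-to-centre distance cutoff.

    Self-pairs are included but an occurrence never pairs with itself; each
    unordered occurrence pair is counted once.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    names = sorted(motif_names)
    index = [pair_name(a, b) for a, b in combinations_with_replacement(names, 2)]
    counts = pd.Series(0.0, index=index)
    lo, hi = window
    inwin = [o for o in occs if lo <= o.start < hi and o.motif in set(names)]
    for i in range(len(inwin)):
        for j in range(i + 1, len(inwin)):
            if abs(inwin[i].center - inwin[j].center) <= cutoff:
                counts[pair_name(inwin[i].motif, inwin[j].motif)] += 1
    return _normalize(counts, hi - lo, normalization)


def _bin_edges(cutoff: int, bin_width: int) -> list[tuple[int, int]]:
    edges = list(range(0, cutoff, bin_width)) + [cutoff]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def pair_distance_binned(
    occs: Iterable[MotifOccurrence],
    window: tuple[int, int],
    motif_names: Sequence[str],
    cutoff: int = 219,
    bin_width: int = 100,
    normalization: str = "per-kb",
) -> pd.Series:
    """Pair counts stratified into centre-to-centre distance bins.

    Bins are [0,b), [b,2b), ..., with the final bin closed at the cutoff
    (truncated if the bin width does not divide the cutoff).
    """
    names = sorted(motif_names)
    bins = _bin_edges(cutoff, bin_width)
    index = [
        f"{pair_name(a, b)}|{lo}-{hi}"
        for a, b in combinations_with_replacement(names, 2)
        for lo, hi in bins
    ]
    counts = pd.Series(0.0, index=index)
    wlo, whi = window
    inwin = [o for o in occs if wlo <= o.start < whi and o.motif in set(names)]
    for i in range(len(inwin)):
        for j in range(i + 1, len(inwin)):
            d = abs(inwin[i].center - inwin[j].center)
            if d > cutoff:
                continue
            b = min(int(d // bin_width), len(bins) - 1)
            lo, hi = bins[b]
            counts[f"{pair_name(inwin[i].motif, inwin[j].motif)}|{lo}-{hi}"] += 1
    return _normalize(counts, whi - wlo, normalization)


_DINUC_NAMES = ["".join(p) for p in product("ACGT", repeat=2)]


def dinucleotide_frequencies(seq: LabelledSequence | str) -> pd.Series:
    """Overlapping dinucleotide frequencies; N-containing positions skipped.

    The denominator is the number of counted (N-free) positions.
    """
    s = seq.seq if isinstance(seq, LabelledSequence) else str(seq)
    if len(s) < 2:
        raise ValueError("window shorter than 2 bp")
    codes = encode(s)
    a, b = codes[:-1], codes[1:]
    valid = (a < 4) & (b < 4)
    counts = np.zeros(16)
    np.add.at(counts, a[valid] * 4 + b[valid], 1)
    denom = valid.sum()
    freqs = counts / denom if denom else counts
    return pd.Series(freqs, index=_DINUC_NAMES)


def gc_content(seq: LabelledSequence | str) -> pd.Series:
    """(#G + #C) / #non-N bases."""
    s = seq.seq if isinstance(seq, LabelledSequence) else str(seq)
    codes = encode(s)
    non_n = (codes < 4).sum()
    if non_n == 0:
        raise ValueError("all-N window has no defined GC content")
    gc = ((codes == 1) | (codes == 2)).sum()
    return pd.Series({"GC": gc / non_n})


def kmer_spectrum(
    seq: LabelledSequence | str, k: int = 4, normalization: str = "per-kb"
) -> pd.Series:
    """Overlapping k-mer counts (N-containing windows skipped)."""
    s = seq.seq if isinstance(seq, LabelledSequence) else str(seq)
    if k > len(s):
        raise ValueError("k exceeds window length")
    names = ["".join(p) for p in product("ACGT", repeat=k)]
    codes = encode(s)
    n = len(codes) - k + 1
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        valid &= col < 4
        idx = idx * 4 + np.where(col < 4, col, 0)
    counts = np.zeros(4**k)
    np.add.at(counts, idx[valid], 1)
    return _normalize(pd.Series(counts, index=names), len(s), normalization)


class SequenceFeaturizer(BaseEstimator, TransformerMixin):
    """Transform whole sequences into a feature matrix.

    Scans each sequence for the configured motifs (one shared FSM for all
    IUPAC motifs) and evaluates the configured feature spaces over the whole
    sequence as a single window. Column order is deterministic: spaces in the
    given order, names sorted within each space.
    """

    def __init__(
        self,
        motifs: Sequence = (),
        spaces: Sequence[FeatureSpace] = (FeatureSpace("motif-frequency"),),
        both_strands: bool = True,
    ):
        self.motifs = motifs
        self.spaces = spaces
        self.both_strands = both_strands

    def fit(self, X=None, y=None) -> "SequenceFeaturizer":
        self.scanner_ = (
            MotifScanner(self.motifs, both_strands=self.both_strands)
            if self.motifs
            else None
        )
        self.feature_names_ = list(
            self._vector(LabelledSequence("_probe", "ACGT" * 8)).index
        )
        return self

    def _vector(self, seq: LabelledSequence) -> pd.Series:
        occs = self.scanner_.scan(seq) if self.scanner_ is not None else []
        window = (0, len(seq))
        names = self.scanner_.motif_names if self.scanner_ is not None else []
        parts = []
        for sp in self.spaces:
            if sp.kind == "motif-frequency":
                parts.append(motif_frequencies(occs, window, names, sp.normalization))
            elif sp.kind == "motif-pair-frequency":
                parts.append(
                    motif_pair_frequencies(
                        occs, window, names, sp.pair_cutoff, sp.normalization
                    )
                )
            elif sp.kind == "motif-pair-distance-binned":
                parts.append(
                    pair_distance_binned(
                        occs, window, names, sp.pair_cutoff, sp.bin_width, sp.normalization
                    )
                )
            elif sp.kind == "dinucleotide-frequency":
                parts.append(dinucleotide_frequencies(seq))
            elif sp.kind == "gc-content":
                parts.append(gc_content(seq))
            elif sp.kind == "kmer-spectrum":
                parts.append(kmer_spectrum(seq, sp.k, sp.normalization))
        return pd.concat(parts) if parts else pd.Series(dtype=float)

    def transform(self, X: Sequence[LabelledSequence]) -> pd.DataFrame:
        rows = {}
        for i, seq in enumerate(X):
            sid = seq.id if isinstance(seq, LabelledSequence) else str(i)
            if not isinstance(seq, LabelledSequence):
                seq = LabelledSequence(sid, str(seq))
            rows[sid] = self._vector(seq)
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.feature_names_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


def features_to_tsv(matrix: pd.DataFrame, path) -> None:
    """Export a feature matrix as TSV (rows = sequences, named columns)."""
    matrix.to_csv(path, sep="\t", index_label="sequence")
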