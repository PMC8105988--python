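"""Hierarchical motif-occurrence combinatorics classifiers (SVM-/RF-MOCCA).

The model trains one multi-class SVM or random forest per motif on the local
sequence landscape around each occurrence of that motif — a 500 bp window
centred at the occurrence, described by local motif occurrence frequencies,
dinucleotide frequencies and GC content. Occurrences classified as the
positive class are then counted per motif and per kilobase, and a log-odds
model over these counts combines them into a whole-sequence score.

Core-CRE prediction refines a positive window: every sub-window delimited by
a pair of positive-classified occurrences (or centred at a single one), with
fixed padding added to each end, is scored, and the sub-window with the
highest score per base pair is reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import dinucleotide_frequencies, gc_content
from .models import (
    ConstantPositiveClassifier,
    LogOddsClassifier,
    MulticlassRF,
    MulticlassSVM,
    _resolve_positive,
)
from .motifs import MotifOccurrence, MotifScanner
from .seqdata import LabelledSequence, encode

__all__ = ["MoccaClassifier", "CorePrediction", "train_mocca"]


@dataclass(frozen=True)
class CorePrediction:
    """A core-CRE interval within a parent window (0-based half-open)."""

    start: int
    end: int
    score: float
    score_per_bp: float
    flagged: bool = False  # True when no positive occurrence was available


class MoccaClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchical per-motif-occurrence CRE classifier.

    Parameters
    ----------
    motifs : sequence of IupacMotif / PwmMotif
        The motif vocabulary. One local classifier is trained per motif.
    base : {"svm", "rf", "positive"}
        Local classifier family. "positive" classifies every occurrence as
        positive, which degenerates the model into a plain log-odds model
        over motif occurrence frequencies (useful for diagnostics).
    positive_label : class label counted as the CRE class.
    window : even local-window size W in bp (default 500); the local window
        of an occurrence is [centre - W/2, centre + W/2), clipped.
    core_padding : padding P added to core-CRE sub-windows (default W/2).
    min_class_occurrences : a motif must have at least this many training
        occurrences in every class to receive its own classifier; motifs
        below the floor are dropped with a warning.
    """

    def __init__(
        self,
        motifs: Sequence = (),
        base: str = "rf",
        positive_label=None,
        window: int = 500,
        core_padding: int | None = None,
        min_class_occurrences: int = 5,
        local_motif_frequencies: bool = True,
        local_dinucleotides: bool = True,
        local_gc: bool = True,
        kernel: str = "quadratic",
        C: float = 1.0,
        n_trees: int = 300,
        max_depth: int | None = None,
        pseudocount: float = 0.1,
        both_strands: bool = True,
        random_state: int = 0,
    ):
        self.motifs = motifs
        self.base = base
        self.positive_label = positive_label
        self.window = window
        self.core_padding = core_padding
        self.min_class_occurrences = min_class_occurrences
        self.local_motif_frequencies = local_motif_frequencies
        self.local_dinucleotides = local_dinucleotides
        self.local_gc = local_gc
        self.kernel = kernel
        self.C = C
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.pseudocount = pseudocount
        self.both_strands = both_strands
        self.random_state = random_state

    # -- local feature extraction -------------------------------------------

    def _local_feature_names(self, motif_names: list[str]) -> list[str]:
        names: list[str] = []
        if self.local_motif_frequencies:
            names += [f"freq:{m}" for m in motif_names]
        if self.local_dinucleotides:
            names += [f"dinuc:{a}{b}" for a in "ACGT" for b in "ACGT"]
        if self.local_gc:
            names.append("gc:GC")
        return names

    def _local_window(self, occ: MotifOccurrence, seq_len: int) -> tuple[int, int]:
        center = (occ.start + occ.end) // 2
        half = self.window // 2
        return max(0, center - half), min(seq_len, center + half)

    def _local_vector(
        self,
        seq: LabelledSequence,
        occ_starts: Mapping[str, np.ndarray],
        occ: MotifOccurrence,
        motif_names: list[str],
    ) -> np.ndarray:
        lo, hi = self._local_window(occ, len(seq))
        kb = (hi - lo) / 1000.0
        parts: list[np.ndarray] = []
        if self.local_motif_frequencies:
            counts = np.array(
                [
                    np.searchsorted(occ_starts[m], hi, side="left")
                    - np.searchsorted(occ_starts[m], lo, side="left")
                    for m in motif_names
                ],
                dtype=float,
            )
            parts.append(counts / kb)
        sub = seq.seq[lo:hi]
        if self.local_dinucleotides:
            parts.append(dinucleotide_frequencies(sub).values)
        if self.local_gc:
            codes = encode(sub)
            non_n = (codes < 4).sum()
            gc = ((codes == 1) | (codes == 2)).sum()
            parts.append(np.array([gc / non_n if non_n else 0.0]))
        return np.concatenate(parts)

    def _scan_all(
        self, seqs: Sequence[LabelledSequence]
    ) -> list[list[MotifOccurrence]]:
        return [self.scanner_.scan(s) for s in seqs]

    @staticmethod
    def _starts_by_motif(
        occs: Sequence[MotifOccurrence], motif_names: list[str]
    ) -> dict[str, np.ndarray]:
        by: dict[str, list[int]] = {m: [] for m in motif_names}
        for o in occs:
            by[o.motif].append(o.start)
        return {m: np.asarray(v, dtype=int) for m, v in by.items()}

    # -- fitting -------------------------------------------------------------

    def _make_local_classifier(self):
        if self.base == "svm":
            return MulticlassSVM(
                kernel=self.kernel, C=self.C, random_state=self.random_state
            )
        if self.base == "rf":
            return MulticlassRF(
                n_trees=self.n_trees,
                max_depth=self.max_depth,
                random_state=self.random_state,
            )
        if self.base == "positive":
            return ConstantPositiveClassifier(self.positive_label_)
        raise ValueError(f"unknown base {self.base!r}")

    def fit(self, X: Sequence[LabelledSequence], y=None) -> "MoccaClassifier":
        seqs = list(X)
        y = np.asarray(y) if y is not None else np.asarray([s.label for s in seqs])
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training requires at least 2 sequence classes")
        self.positive_label_ = _resolve_positive(self.classes_, self.positive_label)
        self.scanner_ = MotifScanner(self.motifs, both_strands=self.both_strands)
        motif_names = self.scanner_.motif_names
        self.local_feature_names_ = self._local_feature_names(motif_names)
        if self.window % 2:
            raise ValueError("local window size must be even")

        occs_per_seq = self._scan_all(seqs)
        # local instances, grouped per motif
        instances: dict[str, list[np.ndarray]] = {m: [] for m in motif_names}
        inst_labels: dict[str, list] = {m: [] for m in motif_names}
        for seq, label, occs in zip(seqs, y, occs_per_seq):
            starts = self._starts_by_motif(occs, motif_names)
            for occ in occs:
                instances[occ.motif].append(
                    self._local_vector(seq, starts, occ, motif_names)
                )
                inst_labels[occ.motif].append(label)

        self.occurrence_classifiers_ = {}
        dropped: list[str] = []
        for m in motif_names:
            labels = np.asarray(inst_labels[m], dtype=object)
            per_class = {c: int((labels == c).sum()) for c in self.classes_}
            if (
                self.base != "positive"
                and min(per_class.values(), default=0) < self.min_class_occurrences
            ):
                dropped.append(m)
                continue
            clf = self._make_local_classifier()
            if self.base == "positive":
                clf.fit()
            else:
                F = pd.DataFrame(
                    np.vstack(instances[m]), columns=self.local_feature_names_
                )
                try:
                    clf.fit(F, labels)
                except ValueError as exc:
                    warnings.warn(
                        f"motif {m!r}: local classifier not fittable ({exc}); dropped"
                    )
                    dropped.append(m)
                    continue
            self.occurrence_classifiers_[m] = clf
        if dropped:
            warnings.warn(
                f"motifs dropped from per-motif modelling (occurrence floor "
                f"{self.min_class_occurrences}): {dropped}"
            )
        if not self.occurrence_classifiers_:
            raise ValueError("all motifs were dropped; no per-motif classifier fittable")
        self.kept_motifs_ = sorted(self.occurrence_classifiers_)

        counts = self._positive_count_matrix(seqs, occs_per_seq)
        y_bin = np.where(y == self.positive_label_, "positive", "negative")
        self.combination_ = LogOddsClassifier(
            pseudocount=self.pseudocount, positive_label="positive"
        ).fit(counts, y_bin)
        return self

    # -- occurrence classification ------------------------------------------

    def _classify_occurrences(
        self, seqs: Sequence[LabelledSequence], occs_per_seq
    ) -> list[list[tuple[MotifOccurrence, bool]]]:
        """Label every occurrence of every kept motif as positive or not."""
        batches: dict[str, list[np.ndarray]] = {m: [] for m in self.kept_motifs_}
        owners: dict[str, list[tuple[int, MotifOccurrence]]] = {
            m: [] for m in self.kept_motifs_
        }
        for si, (seq, occs) in enumerate(zip(seqs, occs_per_seq)):
            starts = self._starts_by_motif(occs, self.scanner_.motif_names)
            for occ in occs:
                if occ.motif in batches:
                    batches[occ.motif].append(
                        self._local_vector(seq, starts, occ, self.scanner_.motif_names)
                    )
                    owners[occ.motif].append((si, occ))
        out: list[list[tuple[MotifOccurrence, bool]]] = [[] for _ in seqs]
        for m in self.kept_motifs_:
            if not batches[m]:
                continue
            F = pd.DataFrame(np.vstack(batches[m]), columns=self.local_feature_names_)
            pred = self.occurrence_classifiers_[m].predict(F)
            for (si, occ), label in zip(owners[m], pred):
                out[si].append((occ, label == self.positive_label_))
        for row in out:
            row.sort(key=lambda t: (t[0].start, t[0].motif, t[0].strand))
        return out

    def classified_occurrences(
        self, seq: LabelledSequence
    ) -> list[tuple[MotifOccurrence, bool]]:
        occs = self.scanner_.scan(seq)
        return self._classify_occurrences([seq], [occs])[0]

    def _positive_count_matrix(
        self, seqs: Sequence[LabelledSequence], occs_per_seq
    ) -> pd.DataFrame:
        classified = self._classify_occurrences(seqs, occs_per_seq)
        rows = np.zeros((len(seqs), len(self.kept_motifs_)))
        col = {m: j for j, m in enumerate(self.kept_motifs_)}
        for i, row in enumerate(classified):
            for occ, is_pos in row:
                if is_pos:
                    rows[i, col[occ.motif]] += 1
        lengths = np.array([len(s) / 1000.0 for s in seqs])
        return pd.DataFrame(
            rows / lengths[:, None],
            columns=self.kept_motifs_,
            index=[s.id for s in seqs],
        )

    # -- scoring -------------------------------------------------------------

    def decision_function(self, X: Sequence[LabelledSequence]) -> np.ndarray:
        seqs = list(X)
        occs_per_seq = self._scan_all(seqs)
        counts = self._positive_count_matrix(seqs, occs_per_seq)
        return self.combination_.decision_function(counts)

    def score_sequence(self, seq: LabelledSequence) -> float:
        return float(self.decision_function([seq])[0])

    def predict(self, X: Sequence[LabelledSequence]) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d > 0, self.positive_label_, f"not-{self.positive_label_}")

    def _combination_score(
        self, pos_starts: Mapping[str, np.ndarray], lo: int, hi: int
    ) -> float:
        kb = (hi - lo) / 1000.0
        vec = np.array(
            [
                (
                    np.searchsorted(pos_starts[m], hi, side="left")
                    - np.searchsorted(pos_starts[m], lo, side="left")
                )
                / kb
                for m in self.kept_motifs_
            ]
        )
        return float(vec @ self.combination_.weights_.values)

    def score_intervals(
        self, seq: LabelledSequence, intervals: Sequence[tuple[int, int]]
    ) -> np.ndarray:
        """Combination scores for sub-intervals of one sequence.

        Occurrences are scanned and classified once for the whole sequence;
        each interval is then scored from the per-kilobase counts of
        positive-classified occurrences whose start lies inside it.
        """
        classified = self.classified_occurrences(seq)
        pos_starts = self._positive_starts(classified)
        return np.array(
            [self._combination_score(pos_starts, lo, hi) for lo, hi in intervals]
        )

    def _positive_starts(self, classified) -> dict[str, np.ndarray]:
        by: dict[str, list[int]] = {m: [] for m in self.kept_motifs_}
        for occ, is_pos in classified:
            if is_pos:
                by[occ.motif].append(occ.start)
        return {m: np.asarray(sorted(v), dtype=int) for m, v in by.items()}

    # -- core-CRE prediction --------------------------------------------------

    def predict_core_cre(
        self, seq: LabelledSequence, region: tuple[int, int] | None = None
    ) -> CorePrediction:
        """Find the highest scoring-per-base-pair sub-window of a region.

        Candidate sub-windows are [start(a)-P, end(b)+P) for every pair
        a < b of positive-classified occurrences in the region, plus
        [centre-P, centre+P) for every single occurrence, clipped to the
        region and deduplicated. Ties are broken towards the shorter, then
        leftmost candidate. When no occurrence is positive-classified, the
        whole region is returned with ``flagged=True``.
        """
        if region is None:
            region = (0, len(seq))
        rlo, rhi = region
        P = self.core_padding if self.core_padding is not None else self.window // 2
        classified = self.classified_occurrences(seq)
        pos_occs = [
            occ for occ, is_pos in classified if is_pos and rlo <= occ.start < rhi
        ]
        pos_starts = self._positive_starts(classified)
        if not pos_occs:
            score = self._combination_score(pos_starts, rlo, rhi)
            return CorePrediction(rlo, rhi, score, score / (rhi - rlo), flagged=True)
        pos_occs.sort(key=lambda o: (o.start, o.end))
        candidates: set[tuple[int, int]] = set()
        for occ in pos_occs:
            center = (occ.start + occ.end) // 2
            candidates.add((max(rlo, center - P), min(rhi, center + P)))
        for i in range(len(pos_occs)):
            for j in range(i + 1, len(pos_occs)):
                a, b = pos_occs[i], pos_occs[j]
                candidates.add((max(rlo, a.start - P), min(rhi, b.end + P)))
        best = None
        for lo, hi in sorted(candidates):
            if hi <= lo:
                continue
            score = self._combination_score(pos_starts, lo, hi)
            key = (-score / (hi - lo), hi - lo, lo)
            if best is None or key < best[0]:
                best = (key, CorePrediction(lo, hi, score, score / (hi - lo)))
        return best[1]


def train_mocca(
    seqs: Sequence[LabelledSequence],
    motifs: Sequence,
    base: str = "rf",
    positive_label=None,
    seed: int = 0,
    **kwargs,
) -> MoccaClassifier:
    """Thin functional wrapper over :class:`MoccaClassifier`."""
    return MoccaClassifier(
        motifs=motifs, base=base, positive_label=positive_label, random_state=seed, **kwargs
    ).fit(seqs)
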