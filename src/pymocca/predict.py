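"""Genome-wide sliding-window prediction, precision-targeted threshold
calibration and validation statistics.

PRC AUC is computed as average precision (step-wise, no trapezoidal
interpolation); ROC AUC uses the Mann-Whitney formulation with ties
averaged. Threshold calibration estimates the expected genome-scale
precision as TP / (TP + w * FP), where w up-weights the calibration
negatives to genome scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score

from .seqdata import LabelledSequence

__all__ = [
    "ScanConfig",
    "Prediction",
    "sliding_windows",
    "scan_genome",
    "calibrate_threshold",
    "validation_stats",
    "crossvalidate",
    "predictions_to_bed",
]


@dataclass
class ScanConfig:
    """Sliding-window scan configuration."""

    window: int = 500
    step: int = 250
    threshold: float | None = None
    merge: bool = True
    core: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window:
            raise ValueError("require 0 < step <= window")


@dataclass
class Prediction:
    """A predicted CRE interval (0-based half-open), optionally with a core."""

    seq_id: str
    start: int
    end: int
    score: float
    core: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("require start < end")
        if self.core is not None:
            clo, chi = self.core
            if not (self.start <= clo < chi <= self.end):
                raise ValueError("core must be contained in the prediction")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def sliding_windows(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Tile [0, length) with fixed-size windows plus a flush-right tail.

    Windows are [i*step, i*step + window); if the final one does not end at
    ``length``, the window [length - window, length) is appended. A sequence
    shorter than the window yields the single clipped window [0, length).
    """
    if window > length:
        return [(0, length)]
    n = (length - window) // step + 1
    out = [(i * step, i * step + window) for i in range(n)]
    if out[-1][1] < length:
        out.append((length - window, length))
    return out


def _merge_windows(
    hits: list[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Merge overlapping/adjacent intervals; merged score is the max member score."""
    merged: list[list] = []
    for lo, hi, score in sorted(hits):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = max(merged[-1][2], score)
        else:
            merged.append([lo, hi, score])
    return [tuple(m) for m in merged]


def scan_genome(
    model,
    genome: Sequence[LabelledSequence],
    config: ScanConfig,
) -> list[Prediction]:
    """Score sliding windows over every chromosome and emit predictions.

    Models exposing ``score_intervals`` (the hierarchical classifiers) have
    their motif occurrences scanned and classified once per chromosome;
    other models are scored on extracted window subsequences.
    """
    if config.threshold is None:
        raise ValueError("scan threshold is unset; calibrate or specify one")
    predictions: list[Prediction] = []
    for chrom in genome:
        windows = sliding_windows(len(chrom), config.window, config.step)
        if hasattr(model, "score_intervals"):
            scores = model.score_intervals(chrom, windows)
        else:
            subs = [
                LabelledSequence(f"{chrom.id}:{lo}-{hi}", chrom.seq[lo:hi])
                for lo, hi in windows
            ]
            scores = model.decision_function(subs)
        hits = [
            (lo, hi, float(s))
            for (lo, hi), s in zip(windows, scores)
            if s >= config.threshold
        ]
        if config.merge:
            hits = _merge_windows(hits)
        for lo, hi, score in hits:
            core = None
            if config.core and hasattr(model, "predict_core_cre"):
                cp = model.predict_core_cre(chrom, region=(lo, hi))
                core = (cp.start, cp.end)
            predictions.append(Prediction(chrom.id, lo, hi, score, core))
    return predictions


def calibrate_threshold(
    positive_scores: Sequence[float],
    negative_scores: Sequence[float],
    precision: float,
    negative_weight: float = 1.0,
) -> float:
    """Smallest observed score whose estimated precision reaches the target.

    Estimated precision at threshold t is TP(t) / (TP(t) + w * FP(t)) with
    TP/FP counted at score >= t and w the genome-scale negative weight. If
    the target is unattainable, max(score) + 1e-6 is returned with a warning.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both calibration sets must be nonempty")
    if not 0 < precision < 1:
        raise ValueError("target precision must be in (0, 1)")
    for t in np.unique(np.concatenate([pos, neg])):
        tp = (pos >= t).sum()
        fp = (neg >= t).sum()
        if tp == 0:
            continue
        if tp / (tp + negative_weight * fp) >= precision:
            return float(t)
    warnings.warn(
        f"target precision {precision} unattainable on the calibration sets; "
        "returning a threshold above every observed score"
    )
    return float(max(pos.max(), neg.max()) + 1e-6)


def validation_stats(y_true, scores, positive_label=None) -> dict:
    """PRC AUC (average precision), ROC AUC and the PR curve points."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if positive_label is not None:
        y = y == positive_label
    y = y.astype(bool)
    if y.all() or not y.any():
        raise ValueError("validation requires both positive and negative labels")
    precision, recall, thresholds = precision_recall_curve(y, s)
    return {
        "prc_auc": float(average_precision_score(y, s)),
        "roc_auc": float(roc_auc_score(y, s)),
        "pr_curve": {
            "precision": precision.tolist(),
            "recall": recall.tolist(),
            "thresholds": thresholds.tolist(),
        },
        "n_positive": int(y.sum()),
        "n_negative": int((~y).sum()),
    }


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    if n < 2:
        return (float("nan"), float("nan"))
    mean = values.mean()
    sem = values.std(ddof=1) / np.sqrt(n)
    half = sstats.t.ppf(0.5 + level / 2, df=n - 1) * sem
    return (float(mean - half), float(mean + half))


def crossvalidate(
    builders: Mapping[str, Callable[[dict[str, list[LabelledSequence]], int], object]],
    data: Mapping[str, Sequence[LabelledSequence]],
    positive_label: str,
    repeats: int = 20,
    n_train: int = 110,
    n_test_positive: int = 50,
    n_test_negative: int = 5000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated random-split cross-validation with PRC AUC per model.

    Per repeat, ``n_train`` sequences per class are drawn for training and
    disjoint test sets of ``n_test_positive`` positives and
    ``n_test_negative`` negatives (split evenly over the negative classes)
    are scored. Each builder is called with the per-class training dict and a
    repeat-specific seed and must return a fitted object exposing
    ``decision_function``. Returns (summary with mean and t-based 95% CI,
    per-repeat PRC AUC table).
    """
    labels = list(data)
    if positive_label not in labels:
        raise ValueError(f"positive label {positive_label!r} not among data classes")
    neg_labels = [l for l in labels if l != positive_label]
    need_pos = n_train + n_test_positive
    if len(data[positive_label]) < need_pos:
        raise ValueError(
            f"insufficient positives: need {need_pos}, have {len(data[positive_label])}"
        )
    per_neg = {
        l: n_test_negative // len(neg_labels) for l in neg_labels
    }
    for l in neg_labels[: n_test_negative % len(neg_labels)]:
        per_neg[l] += 1
    for l in neg_labels:
        need = n_train + per_neg[l]
        if len(data[l]) < need:
            raise ValueError(f"insufficient {l!r} sequences: need {need}, have {len(data[l])}")

    aucs = pd.DataFrame(index=list(builders), columns=range(repeats), dtype=float)
    root = np.random.SeedSequence(seed)
    for r, child in enumerate(root.spawn(repeats)):
        rng = np.random.default_rng(child)
        repeat_seed = int(child.generate_state(1)[0] % (2**31))
        train: dict[str, list[LabelledSequence]] = {}
        test_seqs: list[LabelledSequence] = []
        test_y: list[bool] = []
        for label in labels:
            pool = list(data[label])
            order = rng.permutation(len(pool))
            train[label] = [pool[i] for i in order[:n_train]]
            n_test = n_test_positive if label == positive_label else per_neg[label]
            for i in order[n_train : n_train + n_test]:
                test_seqs.append(pool[i])
                test_y.append(label == positive_label)
        y = np.asarray(test_y)
        for name, build in builders.items():
            model = build(train, repeat_seed)
            scores = np.asarray(model.decision_function(test_seqs), dtype=float)
            aucs.loc[name, r] = average_precision_score(y, scores)
    summary = pd.DataFrame(
        {
            "mean_prc_auc": aucs.mean(axis=1),
            "ci_low": [_t_ci(aucs.loc[m].values)[0] for m in aucs.index],
            "ci_high": [_t_ci(aucs.loc[m].values)[1] for m in aucs.index],
            "repeats": repeats,
        }
    )
    return summary, aucs


def predictions_to_bed(predictions: Sequence[Prediction], path) -> None:
    """Write predictions as BED6, or BED12 with the core as a thick interval."""
    has_core = any(p.core is not None for p in predictions)
    with open(path, "w") as fh:
        for i, p in enumerate(predictions):
            score = int(min(1000, max(0, round(p.score * 100))))
            base = f"{p.seq_id}\t{p.start}\t{p.end}\tcre_{i}\t{score}\t."
            if has_core:
                clo, chi = p.core if p.core is not None else (p.start, p.end)
                block = f"\t{clo}\t{chi}\t0\t1\t{p.end - p.start}\t0"
                fh.write(base + block + "\n")
            else:
                fh.write(base + "\n")
    return None
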