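"""The "auto" pipeline: positives + motifs + genome in, predictions out.

Given only positive training sequences, a motif set and a genome, the
pipeline (1) splits the positives into training and test portions, (2)
trains an N-th order Markov model on the genome and generates dummy-genomic
negatives matched to the positives' length distribution, (3) builds
dummy-CRE negatives by re-planting each positive's motif counts at uniform
positions, (4) trains the requested model, (5) computes validation
statistics on held-out data, (6) calibrates a prediction threshold for a
target expected precision with genome-scale negative weighting, and (7)
scans the genome. Every random draw is derived from one master seed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .mocca import MoccaClassifier
from .models import CREClassifier, cpredictor, dummy_predictor, save_model
from .motifs import MotifScanner
from .predict import (
    Prediction,
    ScanConfig,
    calibrate_threshold,
    predictions_to_bed,
    scan_genome,
    validation_stats,
)
from .seqdata import (
    LabelledSequence,
    MarkovModel,
    generate_sequences,
    randomize_motif_placement,
    train_markov,
)

logger = logging.getLogger("pymocca.auto")

POSITIVE_LABEL = "cre"
MODEL_CHOICES = ("rf-mocca", "svm-mocca", "cpredictor", "dummy-predictor", "svm", "rf")

__all__ = ["AutoConfig", "AutoResult", "run_auto", "stage_seeds"]


@dataclass
class AutoConfig:
    """Configuration of the auto pipeline (defaults documented in docs)."""

    model: str = "rf-mocca"
    train_fraction: float = 0.7
    min_positives: int = 20
    markov_order: int = 4
    test_negatives_per_class: int | None = None  # default: 10x test positives
    calibration_negatives: int = 100
    calibration_negative_length: int = 1000
    precision: float = 0.8
    window: int = 500
    step: int = 250
    predict_cores: bool = False
    n_trees: int = 300
    kernel: str = "quadratic"

    def __post_init__(self) -> None:
        if self.model not in MODEL_CHOICES:
            raise ValueError(f"model must be one of {MODEL_CHOICES}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")


@dataclass
class AutoResult:
    model: object
    threshold: float
    predictions: list[Prediction]
    stats: dict
    train: dict[str, list[LabelledSequence]]
    test: dict[str, list[LabelledSequence]]
    seeds: dict[str, int]
    output_dir: Path | None = None


def stage_seeds(master_seed: int, stages: Sequence[str]) -> dict[str, int]:
    """Fan one master seed out into independent per-stage seeds (< 2^31)."""
    root = np.random.SeedSequence(master_seed)
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(stages, root.spawn(len(stages)))
    }


def _build_model(config: AutoConfig, motifs, seed: int):
    common = dict(positive_label=POSITIVE_LABEL, random_state=seed)
    if config.model in ("rf-mocca", "svm-mocca"):
        return MoccaClassifier(
            motifs=motifs,
            base="rf" if config.model == "rf-mocca" else "svm",
            n_trees=config.n_trees,
            kernel=config.kernel,
            **common,
        )
    if config.model == "cpredictor":
        return cpredictor(motifs, **common)
    if config.model == "dummy-predictor":
        return dummy_predictor(motifs, random_state=seed)
    return CREClassifier(
        motifs=motifs,
        base=config.model,
        n_trees=config.n_trees,
        kernel=config.kernel,
        **common,
    )


def run_auto(
    positives: Sequence[LabelledSequence],
    motifs: Sequence,
    genome: Sequence[LabelledSequence],
    config: AutoConfig | None = None,
    seed: int = 0,
    output_dir=None,
) -> AutoResult:
    config = config or AutoConfig()
    if len(positives) < config.min_positives:
        raise ValueError(
            f"auto mode requires at least {config.min_positives} positive sequences; "
            f"got {len(positives)}"
        )
    seeds = stage_seeds(
        seed, ["split", "genomic-train", "genomic-test", "dummy-cre", "calibration", "model"]
    )
    logger.info("auto: %d positives, %d motifs, genome of %d record(s)",
                len(positives), len(motifs), len(genome))

    # 1. whole-sequence train/test split of the positives (no window leakage)
    rng = np.random.default_rng(seeds["split"])
    order = rng.permutation(len(positives))
    n_train = int(round(config.train_fraction * len(positives)))
    n_train = min(max(n_train, 1), len(positives) - 1)
    pos_train = [positives[i].__class__(positives[i].id, positives[i].seq, POSITIVE_LABEL)
                 for i in order[:n_train]]
    pos_test = [positives[i].__class__(positives[i].id, positives[i].seq, POSITIVE_LABEL)
                for i in order[n_train:]]

    # 2. genome background model and dummy-genomic negatives
    background = train_markov(genome, config.markov_order)
    lengths_train = [len(s) for s in pos_train]
    lengths_test = [len(s) for s in pos_test]
    n_test_neg = config.test_negatives_per_class or 10 * len(pos_test)

    def _genomic(n: int, lengths: list[int], stage: str, prefix: str):
        rng_l = np.random.default_rng(seeds[stage])
        out = []
        for i in range(n):
            length = int(lengths[int(rng_l.integers(len(lengths)))])
            out.extend(
                generate_sequences(
                    background, 1, length,
                    int(rng_l.integers(2**31)),
                    label="dummy-genomic", id_prefix=f"{prefix}{i}_",
                )
            )
        return out

    genomic_train = _genomic(len(pos_train), lengths_train, "genomic-train", "gtrain")
    genomic_test = _genomic(n_test_neg, lengths_test, "genomic-test", "gtest")

    # 3. dummy-CRE negatives: same motif counts as positives, randomised placement
    scanner = MotifScanner(motifs)
    occs = {s.id: scanner.scan(s) for s in positives}
    dummy_train = randomize_motif_placement(
        pos_train, occs, motifs, background, seeds["dummy-cre"]
    )
    dummy_test = randomize_motif_placement(
        pos_test, occs, motifs, background, seeds["dummy-cre"] + 1
    )[:n_test_neg]
    while len(dummy_test) < n_test_neg:  # recycle templates for larger test sets
        extra = randomize_motif_placement(
            pos_test, occs, motifs, background,
            seeds["dummy-cre"] + 2 + len(dummy_test),
        )
        for k, s in enumerate(extra):
            s.id = f"{s.id}_x{len(dummy_test) + k}"
        dummy_test.extend(extra[: n_test_neg - len(dummy_test)])

    train = {
        POSITIVE_LABEL: pos_train,
        "dummy-genomic": genomic_train,
        "dummy-cre": dummy_train,
    }
    test = {
        POSITIVE_LABEL: pos_test,
        "dummy-genomic": genomic_test,
        "dummy-cre": dummy_test,
    }

    # 4. train the model (two-class presets train on positives vs dummy-CREs)
    model = _build_model(config, motifs, seeds["model"])
    if config.model in ("cpredictor", "dummy-predictor"):
        fit_seqs = pos_train + dummy_train
    else:
        fit_seqs = pos_train + genomic_train + dummy_train
    model.fit(fit_seqs)
    logger.info("trained %s on %d sequences", config.model, len(fit_seqs))

    # 5. validation statistics on the held-out sequences
    test_seqs = [s for group in test.values() for s in group]
    y = [s.label == POSITIVE_LABEL for s in test_seqs]
    test_scores = np.asarray(model.decision_function(test_seqs), dtype=float)
    stats = validation_stats(y, test_scores)
    logger.info("held-out PRC AUC %.3f, ROC AUC %.3f", stats["prc_auc"], stats["roc_auc"])

    # 6. precision-targeted threshold with genome-scale negative weighting
    calib_neg = generate_sequences(
        background,
        config.calibration_negatives,
        config.calibration_negative_length,
        seeds["calibration"],
        label="calibration",
        id_prefix="calib",
    )
    genome_length = sum(len(c) for c in genome)
    neg_weight = genome_length / sum(len(s) for s in calib_neg)
    pos_scores = test_scores[: len(pos_test)]
    neg_scores = np.asarray(model.decision_function(calib_neg), dtype=float)
    threshold = calibrate_threshold(pos_scores, neg_scores, config.precision, neg_weight)
    logger.info("calibrated threshold %.4f (negative weight %.2f)", threshold, neg_weight)

    # 7. genome-wide scan
    scan_cfg = ScanConfig(
        window=config.window, step=config.step, threshold=threshold,
        merge=True, core=config.predict_cores,
    )
    predictions = scan_genome(model, genome, scan_cfg)
    logger.info("%d genome-wide prediction(s)", len(predictions))

    result = AutoResult(model, threshold, predictions, stats, train, test, seeds)
    if output_dir is not None:
        result.output_dir = _write_outputs(
            Path(output_dir), model, config, seed, seeds, threshold, stats, predictions
        )
    return result


def _write_outputs(outdir, model, config, master_seed, seeds, threshold, stats, predictions):
    outdir.mkdir(parents=True, exist_ok=True)
    save_model(model, outdir / "model.joblib")
    predictions_to_bed(predictions, outdir / "predictions.bed")
    report = {
        "version": __version__,
        "threshold": threshold,
        "prc_auc": stats["prc_auc"],
        "roc_auc": stats["roc_auc"],
        "n_predictions": len(predictions),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    snapshot = {
        "pymocca_version": __version__,
        "master_seed": int(master_seed),
        "stage_seeds": {k: int(v) for k, v in seeds.items()},
        "config": asdict(config),
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(snapshot, sort_keys=True))
    return outdir
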