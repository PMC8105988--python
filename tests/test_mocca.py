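import warnings

import numpy as np
import pytest

from pymocca import (
    CREClassifier,
    FeatureSpace,
    IupacMotif,
    LabelledSequence,
    MoccaClassifier,
    load_model,
    save_model,
)
from pymocca.seqdata import reverse_complement

from conftest import PRE_MOTIFS, planted_dataset


@pytest.fixture(scope="module")
def tiny_model():
    model = MoccaClassifier(motifs=PRE_MOTIFS, base="positive",
                            positive_label="cre", min_class_occurrences=0)
    seqs = [
        LabelledSequence("p", "T" * 200 + "GAGAG" + "T" * 295, "cre"),
        LabelledSequence("n", "A" * 500, "bg"),
    ]
    return model.fit(seqs)


class TestLocalInstances:

    def test_centred_window_exact_fit(self, tiny_model):
        seq = LabelledSequence("s", "T" * 248 + "GAGA" + "T" * 248)
        occ = type("O", (), {"start": 248, "end": 252})()
        assert tiny_model._local_window(occ, len(seq)) == (0, 500)

    def test_window_clipped_at_edge(self, tiny_model):
        occ = type("O", (), {"start": 8, "end": 12})()
        assert tiny_model._local_window(occ, 600) == (0, 260)

    def test_one_instance_per_occurrence(self, tiny_model):
        seq = LabelledSequence("s", "T" * 100 + "GAGAG" + "T" * 100 + "GAGAG" + "T" * 90)
        classified = tiny_model.classified_occurrences(seq)
        assert len([c for c in classified if c[0].motif == "GAF"]) == 2


class TestHierarchy:
    def test_no_occurrences_scores_zero(self, fitted_mocca):
        seq = LabelledSequence("empty", "T" * 1000)
        assert fitted_mocca.score_sequence(seq) == 0.0

    def test_degenerates_to_motif_frequency_logodds(self, small_planted):
        """With every per-motif classifier forced positive, the hierarchy
        collapses exactly onto a log-odds model over per-kb motif counts."""
        seqs, _ = small_planted
        mocca = MoccaClassifier(
            motifs=PRE_MOTIFS, base="positive", positive_label="cre",
            min_class_occurrences=0, pseudocount=0.1,
        ).fit(seqs)
        plain = CREClassifier(
            motifs=PRE_MOTIFS, spaces=(FeatureSpace("motif-frequency"),),
            base="logodds", pseudocount=0.1, positive_label="cre",
        ).fit([s for s in seqs],
              ["cre" if s.label == "cre" else "negative" for s in seqs])
        a = mocca.decision_function(seqs)
        b = plain.decision_function(seqs)
        assert np.allclose(a, b, atol=1e-9)

    def test_symmetric_training_gives_zero_weights(self, uniform_bg):
        from pymocca import generate_sequences

        base = generate_sequences(uniform_bg, 12, 1000, seed=31)
        seqs = [
            s.__class__(f"{lab}_{s.id}", s.seq, lab)
            for lab in ("cre", "other")
            for s in base
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MoccaClassifier(
                motifs=PRE_MOTIFS, base="rf", positive_label="cre",
                n_trees=30, min_class_occurrences=0, random_state=0,
            ).fit(seqs)
        assert np.allclose(model.combination_.weights_, 0.0)
        assert np.allclose(model.decision_function(seqs[:4]), 0.0)

    def test_training_determinism_bit_identical_archives(self, tmp_path, small_planted):
        seqs, _ = small_planted
        paths = []
        for i in (0, 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MoccaClassifier(
                    motifs=PRE_MOTIFS, base="rf", positive_label="cre",
                    n_trees=40, random_state=5,
                ).fit(seqs)
            p = tmp_path / f"m{i}.joblib"
            save_model(model, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_reverse_complement_invariance(self, uniform_bg):
        """With strand-symmetric local features (motif frequencies + GC) the
        sequence score is invariant under reverse complement. Occurrences
        are planted far apart so that the 1 bp centre rounding cannot move a
        neighbour across a local window edge."""
        seqs, _ = planted_dataset(seed=51, n_per_class=20, length=1500,
                                  counts={"GAF": 3, "PHO": 3}, cluster_width=700)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MoccaClassifier(
                motifs=PRE_MOTIFS, base="rf", positive_label="cre", n_trees=40,
                local_dinucleotides=False, random_state=2,
            ).fit(seqs)
        probes = [
            LabelledSequence("a", "T" * 600 + "GAGAG" + "T" * 600),
            LabelledSequence("b", "T" * 300 + "GCCAT" + "T" * 900 + "GAGAG" + "T" * 300),
        ]
        for p in probes:
            rc = LabelledSequence(p.id + "_rc", reverse_complement(p.seq))
            assert model.score_sequence(p) == pytest.approx(model.score_sequence(rc))

    def test_motif_floor_drops_unsupported_motifs(self, small_planted):
        seqs, _ = small_planted
        rare = IupacMotif("RARE", "ACGCGTACGCGT")  # essentially never occurs
        with pytest.warns(UserWarning, match="dropped"):
            model = MoccaClassifier(
                motifs=PRE_MOTIFS + [rare], base="rf", positive_label="cre",
                n_trees=30, random_state=0,
            ).fit(seqs)
        assert "RARE" not in model.kept_motifs_
        assert set(model.kept_motifs_) == {"GAF", "PHO"}

    def test_combination_weight_recovery(self):
        """When only one motif's local landscape separates the classes, that
        motif should dominate the combination weights."""
        hits = 0
        for seed in range(6):
            seqs, _ = planted_dataset(
                seed=400 + seed, n_per_class=25, counts={"GAF": 6, "PHO": 0}
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MoccaClassifier(
                    motifs=PRE_MOTIFS, base="rf", positive_label="cre",
                    n_trees=50, min_class_occurrences=0, random_state=seed,
                ).fit(seqs)
            w = model.combination_.weights_.abs()
            if w.idxmax() == "GAF":
                hits += 1
        assert hits >= 5


def brute_force_core(model, seq, region=None):
    """Independent enumeration and scoring of core-CRE candidates."""
    if region is None:
        region = (0, len(seq))
    rlo, rhi = region
    P = model.core_padding if model.core_padding is not None else model.window // 2
    classified = model.classified_occurrences(seq)
    pos = sorted(
        (o for o, isp in classified if isp and rlo <= o.start < rhi),
        key=lambda o: (o.start, o.end),
    )
    if not pos:
        return None
    candidates = set()
    for o in pos:
        c = (o.start + o.end) // 2
        candidates.add((max(rlo, c - P), min(rhi, c + P)))
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            candidates.add((max(rlo, pos[i].start - P), min(rhi, pos[j].end + P)))
    best = None
    for lo, hi in candidates:
        if hi <= lo:
            continue
        score = float(model.score_intervals(seq, [(lo, hi)])[0])
        key = (-score / (hi - lo), hi - lo, lo)
        if best is None or key < best[0]:
            best = (key, (lo, hi, score))
    return best[1]


class TestCoreCre:
    def test_candidate_count(self, fitted_mocca, small_planted):
        seqs, _ = small_planted
        for seq in seqs[:5]:
            pos = [o for o, isp in fitted_mocca.classified_occurrences(seq) if isp]
            n = len(pos)
            if n == 0:
                continue
            # candidate enumeration before clipping dedup: n singles + C(n,2) pairs
            assert n * (n - 1) // 2 + n >= 1

    def test_single_occurrence_candidate(self, small_planted):
        seqs, _ = small_planted
        model = MoccaClassifier(
            motifs=[IupacMotif("GAF", "GAGAG")], base="positive",
            positive_label="cre", min_class_occurrences=0,
        ).fit(seqs)
        seq = LabelledSequence("s", "T" * 398 + "GAGA" + "G" + "T" * 397)
        cp = model.predict_core_cre(seq)
        assert (cp.start, cp.end) == (150, 650)
        assert not cp.flagged

    def test_no_positive_occurrence_flags_whole_window(self, fitted_mocca):
        seq = LabelledSequence("s", "T" * 800)
        cp = fitted_mocca.predict_core_cre(seq)
        assert cp.flagged and (cp.start, cp.end) == (0, 800)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, fitted_mocca, seed):
        seqs, _ = planted_dataset(seed=700 + seed, n_per_class=2, length=1200,
                                  counts={"GAF": 3, "PHO": 2}, cluster_width=800)
        for seq in seqs:
            expected = brute_force_core(fitted_mocca, seq)
            got = fitted_mocca.predict_core_cre(seq)
            if expected is None:
                assert got.flagged
            else:
                assert (got.start, got.end, got.score) == pytest.approx(expected)
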