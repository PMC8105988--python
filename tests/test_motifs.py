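import math

import numpy as np
import pytest

from pymocca import (
    IupacMotif,
    LabelledSequence,
    MarkovModel,
    PwmMotif,
    calibrate_pwm_threshold,
    parse_motif_xml,
    parse_pssm_file,
    scan_iupac,
    scan_pwm,
)
from pymocca.motifs import MotifScannerFsm, build_fsm, reverse_complement_iupac
from pymocca.seqdata import generate_sequences

from helpers import naive_scan, random_iupac_motifs


class TestIupacMotif:
    def test_invalid_code_names_position(self):
        with pytest.raises(ValueError, match="invalid IUPAC code 'X' at position 4"):
            IupacMotif("GAF", "GAGAX")

    def test_reverse_complement_of_degenerate_pattern(self):
        assert reverse_complement_iupac("RYGN") == "NCRY"


class TestMotifXml:
    def test_single_motif(self, tmp_path):
        p = tmp_path / "m.xml"
        p.write_text('<motifs><motif name="GAF" iupac="GAGAG"/></motifs>')
        (m,) = parse_motif_xml(p)
        assert (m.name, m.pattern, m.mismatches) == ("GAF", "GAGAG", 0)

    def test_invalid_pattern_rejected(self, tmp_path):
        p = tmp_path / "m.xml"
        p.write_text('<motifs><motif name="GAF" iupac="GAGAX"/></motifs>')
        with pytest.raises(ValueError, match="invalid IUPAC"):
            parse_motif_xml(p)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "m.xml"
        p.write_text(
            '<motifs><motif name="a" iupac="AC"/><motif name="a" iupac="GG"/></motifs>'
        )
        with pytest.raises(ValueError, match="duplicate"):
            parse_motif_xml(p)

    def test_shipped_example_parses(self):
        from importlib.resources import files

        motifs = parse_motif_xml(files("pymocca") / "examples" / "example_motifs.xml")
        assert {m.name for m in motifs} >= {"GAF", "PHO"}


class TestPssmParsing:
    def test_uniform_column_gives_zero_log_odds(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(">m\nA | 1 1\nC | 1 1\nG | 1 1\nT | 1 1\n")
        (pwm,) = parse_pssm_file(p)
        assert np.allclose(pwm.matrix, 0.0)

    def test_pseudocount_smoothing_log_odds(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(">m\nA | 3\nC | 0\nG | 0\nT | 1\n")
        (pwm,) = parse_pssm_file(p, pseudocount=1.0)
        assert pwm.matrix[0, 0] == pytest.approx(math.log(2.0), abs=1e-12)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text("")
        assert parse_pssm_file(p) == []

    def test_unequal_rows_rejected(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(">m\nA | 1 2\nC | 1\nG | 1 2\nT | 1 2\n")
        with pytest.raises(ValueError, match="unequal"):
            parse_pssm_file(p)

    def test_negative_entries_rejected(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(">m\nA | -1\nC | 1\nG | 1\nT | 1\n")
        with pytest.raises(ValueError, match="negative"):
            parse_pssm_file(p)

    def test_shipped_example_parses(self):
        from importlib.resources import files

        pwms = parse_pssm_file(files("pymocca") / "examples" / "example_pwms.txt")
        assert [len(p) for p in pwms] == [6, 6]


class TestFsmScanning:
    def test_single_letter_motif(self):
        fsm = build_fsm([IupacMotif("a", "A")])
        occs = fsm.scan("AAA", both_strands=False)
        assert [o.start for o in occs] == [0, 1, 2]

    def test_overlapping_matches_reported(self):
        fsm = build_fsm([IupacMotif("GAF", "GAGAG")])
        occs = [o for o in fsm.scan("TTGAGAGAGTT") if o.strand == "+"]
        assert [o.start for o in occs] == [2, 4]

    def test_two_motifs_in_parallel(self):
        fsm = build_fsm([IupacMotif("m1", "AC"), IupacMotif("m2", "CA")])
        occs = fsm.scan("ACA", both_strands=False)
        assert [(o.motif, o.start) for o in occs] == [("m1", 0), ("m2", 1)]

    def test_both_strands_forward_coordinates(self):
        # GAGAG's reverse complement CTCTC is absent, so all hits are '+'
        fsm = build_fsm([IupacMotif("GAF", "GAGAG")])
        occs = fsm.scan("TTGAGAGAGTT", both_strands=True)
        assert {o.strand for o in occs} == {"+"}
        occs_rc = fsm.scan("AACTCTCTCAA", both_strands=True)
        assert {(o.start, o.strand) for o in occs_rc} == {(2, "-"), (4, "-")}

    def test_palindromic_motif_reported_once(self):
        fsm = build_fsm([IupacMotif("pal", "GTAC")])
        occs = fsm.scan("GGTACC", both_strands=True)
        assert len(occs) == 1 and occs[0].strand == "+"

    def test_n_matches_nothing(self):
        fsm = build_fsm([IupacMotif("n", "NN"), IupacMotif("a", "A", mismatches=1)])
        assert fsm.scan("NNNN") == []

    def test_mismatch_budget(self):
        fsm = build_fsm([IupacMotif("m", "AAAA", mismatches=1)])
        starts = {o.start for o in fsm.scan("AATAAA", both_strands=False)}
        assert starts == {0, 1, 2}

    @pytest.mark.parametrize("trial", range(30))
    def test_fsm_equals_naive_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        motifs = random_iupac_motifs(rng)
        seq = "".join(rng.choice(list("ACGTN"), size=2000, p=[0.24] * 4 + [0.04]))
        got = {
            (o.motif, o.start, o.end, o.strand)
            for o in MotifScannerFsm(motifs).scan(seq)
        }
        assert got == naive_scan(motifs, seq)

    def test_scan_linearity_on_concatenation(self):
        rng = np.random.default_rng(77)
        motifs = random_iupac_motifs(rng, n_max=4)
        s1 = "".join(rng.choice(list("ACGT"), size=500))
        s2 = "".join(rng.choice(list("ACGT"), size=500))
        fsm = MotifScannerFsm(motifs)
        inside_s1 = {
            (o.motif, o.start, o.end, o.strand)
            for o in fsm.scan(s1 + s2)
            if o.end <= len(s1)
        }
        alone = {(o.motif, o.start, o.end, o.strand) for o in fsm.scan(s1)}
        assert inside_s1 == alone


class TestPwmScanning:
    def test_threshold_required(self):
        pwm = PwmMotif("m", np.zeros((4, 4)))
        with pytest.raises(ValueError, match="threshold"):
            scan_pwm(pwm, "ACGTACGTAC")

    def test_low_threshold_counts_all_offsets(self):
        pwm = PwmMotif("m", np.random.default_rng(0).normal(size=(4, 4)), threshold=-1e9)
        occs = scan_pwm(pwm, "ACGTACGTAC", both_strands=False)
        assert len(occs) == 7

    def test_zero_matrix_zero_threshold_matches_everywhere(self):
        pwm = PwmMotif("m", np.zeros((4, 3)), threshold=0.0)
        occs = scan_pwm(pwm, "ACGTACGT", both_strands=False)
        assert len(occs) == 6 and all(o.score == 0.0 for o in occs)

    def test_max_threshold_matches_planted_site_only(self):
        matrix = np.full((4, 4), -2.0)
        for i, base in enumerate("ACGT"):  # strongly favour ACGT
            matrix["ACGT".index(base), i] = 1.0
        pwm = PwmMotif("m", matrix, threshold=4.0)
        occs = scan_pwm(pwm, "GGACGTGG", both_strands=False)
        assert [(o.start, o.score) for o in occs] == [(2, 4.0)]

    def test_n_windows_skipped(self):
        pwm = PwmMotif("m", np.zeros((4, 3)), threshold=-1.0)
        occs = scan_pwm(pwm, "ACNGTACG", both_strands=False)
        assert all(not set("ACNGTACG"[o.start : o.end]) & {"N"} for o in occs)

    def test_reverse_strand_scores_match_rc_matrix(self):
        rng = np.random.default_rng(5)
        pwm = PwmMotif("m", rng.normal(size=(4, 5)), threshold=-1e9)
        seq = "ACGGTTACAGTC"
        minus = {o.start: o.score for o in scan_pwm(pwm, seq) if o.strand == "-"}
        fwd_on_rc = PwmMotif("m", pwm.rc_matrix(), threshold=-1e9)
        expected = {o.start: o.score for o in scan_pwm(fwd_on_rc, seq, both_strands=False)}
        assert minus == pytest.approx(expected)


@pytest.fixture(scope="module")
def pwm():
    counts = np.array(
        [
            [2, 18, 1, 17, 2, 16],
            [1, 1, 1, 1, 1, 2],
            [16, 0, 17, 1, 16, 1],
            [1, 1, 1, 1, 1, 1],
        ]
    )
    return PwmMotif.from_counts("gafpwm", counts)


class TestPwmCalibration:

    def test_deterministic(self, pwm):
        t1 = calibrate_pwm_threshold(pwm, target_rate=1.0, total_length=100_000, seed=3)
        t2 = calibrate_pwm_threshold(pwm, target_rate=1.0, total_length=100_000, seed=3)
        assert t1 == t2

    def test_monotone_in_target_rate(self, pwm):
        rates = [0.2, 1.0, 5.0, 25.0]
        thresholds = [
            calibrate_pwm_threshold(pwm, target_rate=r, total_length=100_000, seed=3)
            for r in rates
        ]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_saturating_rate_matches_nearly_all_windows(self, pwm):
        calibrate_pwm_threshold(pwm, target_rate=1990.0, total_length=20_000, seed=1)
        (seq,) = generate_sequences(MarkovModel.uniform(0), 1, 5000, seed=2)
        occs = scan_pwm(pwm, seq)
        assert len(occs) >= 2 * (5000 - len(pwm) + 1) * 0.97

    def test_infeasible_rate_rejected(self, pwm):
        with pytest.raises(ValueError, match="windows"):
            calibrate_pwm_threshold(pwm, target_rate=5000.0, total_length=10_000, seed=1)
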