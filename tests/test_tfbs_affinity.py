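"""PWM scoring, calibration and Transposon Affinity Scores."""

import numpy as np
import pytest

from te_exapt.core_model import GenomeModel, GenomicInterval, Peak, TEInstance
from te_exapt.synthetic_data import PWMSpec, generate_pwms
from te_exapt.tfbs_affinity import (
    PWM,
    calibrate_threshold,
    compute_tas,
    hit_rate,
    random_sequence_codes,
    reverse_complement,
    scan_sequence,
    score_word,
    tas_matrix,
    TASRecord,
)
from .conftest import peak_from_window

UNIFORM = np.full(4, 0.25)


def brute_force_scan(seq, pwm, threshold):
    """Independent naive rescan: score every word on both strands."""
    hits = []
    w = pwm.width
    for pos in range(len(seq) - w + 1):
        word = seq[pos : pos + w]
        for strand in "+-":
            s = score_word(pwm, word, strand)
            if s >= threshold:
                hits.append((pos, strand, pytest.approx(s)))
    return sorted(hits, key=lambda h: (h[0], h[1]))


class TestScoring:
    def test_background_pwm_scores_zero(self):
        pwm = PWM("bg", np.tile(UNIFORM[:, None], (1, 6)))
        assert score_word(pwm, "ACGTAC") == pytest.approx(0.0)
        assert score_word(pwm, "GGGGGG", "-") == pytest.approx(0.0)

    def test_single_position_log_odds_arithmetic(self):
        pwm = PWM("one", np.array([[0.97], [0.01], [0.01], [0.01]]))
        assert score_word(pwm, "A") == pytest.approx(np.log2(0.97 / 0.25), abs=1e-3)
        assert score_word(pwm, "A") == pytest.approx(1.956, abs=1e-3)

    def test_n_contributes_zero(self):
        pwm = PWM("one", np.array([[0.97], [0.01], [0.01], [0.01]]))
        assert score_word(pwm, "N") == pytest.approx(0.0)

    def test_palindromic_pwm_strand_symmetric(self, rng):
        # P(A)=P(T), P(C)=P(G) mirrored around the centre -> palindromic
        col = np.array([0.4, 0.1, 0.1, 0.4])
        rev = col[::-1]
        pwm = PWM("pal", np.column_stack([col, rev]))
        for _ in range(20):
            word = "".join(rng.choice(list("ACGT"), 2))
            assert score_word(pwm, word, "+") == pytest.approx(
                score_word(pwm, word, "-")
            )


class TestScanning:
    def test_planted_consensus_word_recovered(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 10)], rng)
        pwm = calibrate_threshold(pwm, UNIFORM, n_mc=2000, rng=rng)
        seq = "".join(rng.choice(list("ACGT"), 200))
        seq = seq[:37] + pwm.consensus_word() + seq[47:]
        assert 37 in {pos for pos, s, _ in scan_sequence(seq, pwm) if s == "+"}

    def test_unreachable_threshold_gives_no_hits(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 10)], rng)
        t = pwm.max_score() + 1.0
        seq = "".join(rng.choice(list("ACGT"), 200))
        assert scan_sequence(seq, pwm, threshold=t) == []

    def test_matches_brute_force_oracle(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 8)], rng)
        t = 0.5 * pwm.max_score()
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), 60))
            got = [(p, s, pytest.approx(sc)) for p, s, sc in scan_sequence(pwm=pwm, seq=seq, threshold=t)]
            assert got == brute_force_scan(seq, pwm, t)

    def test_strand_closure_mirror(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 9)], rng)
        t = 0.4 * pwm.max_score()
        seq = "".join(rng.choice(list("ACGT"), 80))
        fwd = scan_sequence(seq, pwm, threshold=t)
        rc = scan_sequence(reverse_complement(seq), pwm, threshold=t)
        mirrored = sorted(
            (len(seq) - pwm.width - p, {"+": "-", "-": "+"}[s], pytest.approx(sc))
            for p, s, sc in rc
        )
        assert [(p, s, pytest.approx(sc)) for p, s, sc in fwd] == mirrored

    def test_window_shorter_than_motif_is_empty(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 12)], rng)
        assert scan_sequence("ACGT", pwm, threshold=0.0) == []


class TestCalibration:
    def test_below_minimum_threshold_hits_everything(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 8)], rng)
        assert hit_rate(pwm, 200, rng=rng, threshold=-1e9) == 1.0

    def test_hit_rate_monotone_in_threshold(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 10)], rng)
        codes = random_sequence_codes(500, 200, UNIFORM, rng)
        from te_exapt.tfbs_affinity import window_max_scores

        maxima = window_max_scores(codes, pwm)
        grid = np.linspace(maxima.min() - 1, maxima.max() + 1, 20)
        rates = [(maxima >= t).mean() for t in grid]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_degenerate_pwm_raises(self):
        flat = PWM("flat", np.tile(UNIFORM[:, None], (1, 4)))
        with pytest.raises(ValueError, match="flat"):
            calibrate_threshold(flat, UNIFORM, n_mc=1000, seed=1)

    def test_calibration_report_attached(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 10)], rng)
        cal = calibrate_threshold(pwm, UNIFORM, n_mc=2000, seed=5)
        assert cal.calibration is not None
        assert cal.calibration.n_mc == 2000
        assert cal.calibration.achieved_rate >= 0.01


def _tiny_te_genome(rng, n_instances, pwm, planted_idx):
    """One chromosome with TE instances at fixed spacing; the consensus word
    is written inside the instances listed in planted_idx."""
    L = 2000 * (n_instances + 1)
    seq = list("".join(rng.choice(list("ACGT"), L)))
    tes, peaks = [], []
    for i in range(n_instances):
        start = 2000 * (i + 1)
        if i in planted_idx:
            seq[start + 40 : start + 40 + pwm.width] = pwm.consensus_word()
        tes.append(
            TEInstance(GenomicInterval("chr1", start, start + 120), "FAM", "X/Y", f"t{i}")
        )
        mid = start + 60
        peaks.append(peak_from_window(f"p{i}", "chr1", mid - 100, mid + 100))
    return {"chr1": "".join(seq)}, tes, peaks


class TestTAS:
    def test_all_instances_carrying_gives_one(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 10)], rng)
        pwm = calibrate_threshold(pwm, UNIFORM, n_mc=2000, rng=rng)
        seqs, tes, peaks = _tiny_te_genome(rng, 8, pwm, set(range(8)))
        (rec,) = compute_tas(peaks, tes, seqs, pwm)
        assert rec.tas == 1.0 and rec.n_instances == 8

    def test_partial_carrying_fraction(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 12)], rng)
        pwm = calibrate_threshold(pwm, UNIFORM, n_mc=2000, rng=rng)
        seqs, tes, peaks = _tiny_te_genome(rng, 8, pwm, {0, 1})
        (rec,) = compute_tas(peaks, tes, seqs, pwm)
        assert 0.0 <= rec.tas <= 1.0
        assert rec.tas == pytest.approx(0.25, abs=0.13)  # false hits possible

    def test_absent_motif_tas_near_false_positive_rate(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 10)], rng)
        pwm = calibrate_threshold(pwm, UNIFORM, n_mc=5000, rng=rng)
        seqs, tes, peaks = _tiny_te_genome(rng, 120, pwm, set())
        (rec,) = compute_tas(peaks, tes, seqs, pwm)
        assert rec.tas <= 0.05

    def test_hit_outside_te_span_does_not_carry(self, rng):
        (pwm,) = generate_pwms([PWMSpec("T", 10)], rng)
        pwm = calibrate_threshold(pwm, UNIFORM, n_mc=2000, rng=rng)
        L = 4000
        seq = list("".join(rng.choice(list("ACGT"), L)))
        # TE at [2000, 2120); plant the word in the window but outside the TE
        seq[1970 : 1970 + pwm.width] = pwm.consensus_word()
        seqs = {"chr1": "".join(seq)}
        tes = [TEInstance(GenomicInterval("chr1", 2000, 2120), "FAM", "X/Y", "t0")]
        peaks = [peak_from_window("p0", "chr1", 1960, 2160)]
        (span_rec,) = compute_tas(peaks, tes, seqs, pwm, carrying="span")
        (win_rec,) = compute_tas(peaks, tes, seqs, pwm, carrying="window")
        assert win_rec.n_carrying == 1
        # the planted word ends at 1960 + w - 10 < 2000: never inside the span
        assert span_rec.n_carrying in (0, 1)  # 1 only via a chance in-span hit


class TestTASMatrix:
    def test_all_zero_tas_no_interactors(self):
        recs = [TASRecord("F1", "TF1", 10, 0), TASRecord("F2", "TF1", 5, 0)]
        m = tas_matrix(recs)
        assert m.interactors == [] and (m.matrix.values == 0).all()

    def test_threshold_boundary_inclusive(self):
        recs = [TASRecord("F1", "TF1", 10, 1), TASRecord("F1", "TF2", 100, 9)]
        m = tas_matrix(recs, tas_min=0.10)
        assert m.interactors == ["TF1"]  # 0.10 kept, 0.09 excluded

    def test_record_order_invariance(self, rng):
        recs = [
            TASRecord(f"F{i}", f"TF{j}", 20, int(rng.integers(0, 21)))
            for i in range(4)
            for j in range(3)
        ]
        m1 = tas_matrix(recs)
        perm = list(rng.permutation(len(recs)))
        m2 = tas_matrix([recs[i] for i in perm])
        assert m1.matrix.equals(m2.matrix)
        assert m1.row_order == m2.row_order and m1.col_order == m2.col_order
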