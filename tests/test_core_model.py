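"""Interval algebra, window construction and format I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from te_exapt.core_model import (
    GenomicInterval,
    Peak,
    make_window,
    overlaps,
    partition_peaksets,
    read_peaks,
    read_pwms,
    read_repeatmasker,
    write_peaks_bed,
)
from .conftest import peak_from_window, random_interval


def brute_force_overlap(a, b):
    """Per-base set-intersection oracle."""
    if a.chrom != b.chrom:
        return False
    return bool(set(range(a.start, a.end)) & set(range(b.start, b.end)))


class TestIntervals:
    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 50)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 50)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 100, 200), ("chr1", 199, 300), True),  # one shared base
            (("chr1", 100, 200), ("chr1", 200, 300), False),  # half-open adjacency
            (("chr1", 100, 200), ("chr2", 100, 200), False),
        ],
    )
    def test_overlap_examples(self, a, b, expected):
        assert overlaps(GenomicInterval(*a), GenomicInterval(*b)) is expected

    def test_overlap_matches_per_base_oracle(self, rng):
        for _ in range(1000):
            a = random_interval(rng)
            b = random_interval(rng)
            assert overlaps(a, b) == brute_force_overlap(a, b)
            assert overlaps(a, b) == overlaps(b, a)  # symmetry

    @given(start=st.integers(0, 10_000), length=st.integers(1, 500))
    @settings(deadline=None, max_examples=50)
    def test_disjoint_translates_never_overlap(self, start, length):
        a = GenomicInterval("chr1", start, start + length)
        b = GenomicInterval("chr1", start + length, start + 2 * length)
        assert not overlaps(a, b)


class TestWindows:
    def test_window_centered_on_midpoint(self):
        w, clipped = make_window(GenomicInterval("chr1", 1000, 1400))
        assert (w.start, w.end) == (1100, 1300) and not clipped

    def test_degenerate_single_base_peak(self):
        w, _ = make_window(GenomicInterval("chr1", 1000, 1001))
        assert (w.start, w.end) == (900, 1100)

    def test_clipping_is_flagged_not_silent(self):
        w, clipped = make_window(GenomicInterval("chr1", 0, 20), 200, chrom_length=5000)
        assert clipped and w.start == 0 and w.length < 200
        w2, clipped2 = make_window(
            GenomicInterval("chr1", 4980, 5000), 200, chrom_length=5000
        )
        assert clipped2 and w2.end == 5000


class TestPeakIO:
    def test_read_peaks_assigns_ids_and_windows(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text(
            "".join(f"chr1\t{1000 + i * 500}\t{1400 + i * 500}\n" for i in range(20))
        )
        peaks, report = read_peaks(path)
        assert len(peaks) == 20 and report.rows_read == 20
        assert [p.id for p in peaks][:2] == ["peak_0001", "peak_0002"]
        assert peaks[0].window.start == 1100 and peaks[0].window.end == 1300

    def test_malformed_rows_rejected_and_logged(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t1000\t1400\nchr1\t500\t400\nchr1\tx\t9\n")
        peaks, report = read_peaks(path)
        assert len(peaks) == 1 and report.rows_skipped == 2

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("# only a comment\n")
        with pytest.raises(ValueError):
            read_peaks(path)

    def test_bed_round_trip_identity(self, tmp_path, rng):
        peaks = [
            peak_from_window(f"p{i}", "chr1", s, s + 200)
            for i, s in enumerate(rng.integers(0, 10_000, 15))
        ]
        path = tmp_path / "rt.bed"
        write_peaks_bed(peaks, path)
        back, _ = read_peaks(path)
        assert [(p.id, p.interval) for p in back] == [
            (p.id, p.interval) for p in peaks
        ]


class TestRepeatMaskerIO:
    RM_HEADER = (
        "   SW  perc perc perc  query     position in query    matching repeat\n"
        "score  div. del. ins.  sequence  begin  end  (left)   repeat  class/family\n"
        "\n"
    )

    def test_one_based_conversion_and_header_skip(self, tmp_path):
        rows = "".join(
            f"  225  25.0  0.0  0.0  chr1  {1001 + i * 300}  {1100 + i * 300}  "
            f"(0)  +  MIRb  SINE/MIR  1  100  (0)  {i}\n"
            for i in range(10)
        )
        path = tmp_path / "rm.out"
        path.write_text(self.RM_HEADER + rows)
        tes, report = read_repeatmasker(path, dialect="rm_out")
        assert len(tes) == 10 and report.rows_read == 10
        assert tes[0].interval.start == 1000 and tes[0].interval.end == 1100
        assert tes[0].name == "MIRb" and tes[0].te_class == "SINE/MIR"

    def test_bed_dialect(self, tmp_path):
        path = tmp_path / "te.bed"
        path.write_text("chr2\t500\t700\tMIRb\tSINE/MIR\n")
        tes, _ = read_repeatmasker(path, dialect="bed_name_class")
        assert tes[0].name == "MIRb" and tes[0].te_class == "SINE/MIR"
        assert tes[0].interval == GenomicInterval("chr2", 500, 700, ".")

    def test_unknown_dialect_and_missing_class(self, tmp_path):
        path = tmp_path / "te.bed"
        path.write_text("chr2\t500\t700\tMIRb\n")
        with pytest.raises(ValueError):
            read_repeatmasker(path, dialect="nope")
        with pytest.raises(ValueError):
            read_repeatmasker(path, dialect="bed_name_class")


class TestPWMIO:
    def test_jaspar_pseudocount_normalisation(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0001.1 T1\nA [ 8 0 ]\nC [ 0 8 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        )
        (pwm,) = read_pwms(path, format="jaspar")
        assert pwm.width == 2
        assert pwm.probs[0, 0] == pytest.approx((8 + 0.25) / 9)
        assert pwm.probs[1, 1] == pytest.approx((8 + 0.25) / 9)

    def test_transfac_uniform_position(self, tmp_path):
        path = tmp_path / "m.transfac"
        path.write_text(
            "ID  T1\nBF  none\nP0      A      C      G      T\n"
            "01      2      2      2      2\n"
            "02      0      8      0      0\nXX\n//\n"
        )
        (pwm,) = read_pwms(path, format="transfac")
        assert np.allclose(pwm.probs[:, 0], 0.25)

    def test_three_matrices_distinct_ids(self, tmp_path):
        block = ">MA000{i}.1 T{i}\nA [ 4 0 ]\nC [ 0 4 ]\nG [ 2 2 ]\nT [ 2 2 ]\n"
        path = tmp_path / "m.jaspar"
        path.write_text("".join(block.format(i=i) for i in range(1, 4)))
        pwms = read_pwms(path, format="jaspar")
        assert len(pwms) == 3 and len({p.id for p in pwms}) == 3


class TestPartition:
    def test_multiplicity_asymmetry(self):
        a = [peak_from_window("a0", "chr1", 0, 200)]
        b = [
            peak_from_window("b0", "chr1", 100, 300),
            peak_from_window("b1", "chr1", 150, 350),
        ]
        part = partition_peaksets(a, b)
        assert part.counts["A_and_B"] == 1 and part.counts["B_and_A"] == 2

    def test_disjoint_sets(self):
        a = [peak_from_window("a0", "chr1", 0, 200)]
        b = [peak_from_window("b0", "chr1", 1000, 1200)]
        part = partition_peaksets(a, b)
        assert part.a_only == a and part.b_only == b and not part.a_and_b

    def test_matches_all_pairs_oracle_and_partitions_exactly(self, rng):
        a = [
            peak_from_window(f"a{i}", "chr1", s, s + 200)
            for i, s in enumerate(rng.integers(0, 5_000, 50))
        ]
        b = [
            peak_from_window(f"b{i}", "chr1", s, s + 200)
            for i, s in enumerate(rng.integers(0, 5_000, 50))
        ]
        part = partition_peaksets(a, b)
        oracle_a = [p for p in a if any(overlaps(p.window, q.window) for q in b)]
        oracle_b = [q for q in b if any(overlaps(q.window, p.window) for p in a)]
        assert part.a_and_b == oracle_a and part.b_and_a == oracle_b
        assert len(part.a_only) + len(part.a_and_b) == len(a)
        assert len(part.b_only) + len(part.b_and_a) == len(b)
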