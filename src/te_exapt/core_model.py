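"""Domain types, coordinate conventions, interval algebra and file I/O.

Every located feature in the package uses 0-based, half-open coordinates
(``[start, end)``), the BED convention.  RepeatMasker ``.out`` files, which
are 1-based inclusive, are converted on read.  Peaks carry a fixed-size
analysis window (200 bp by default) centred on the geometric midpoint of
the called interval; all sequence scanning downstream operates on that
window, as does peak-set intersection bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

DEFAULT_WINDOW_SIZE = 200


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A located span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Geometric midpoint, ``floor((start+end)/2)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open convention: ``[100,200)`` and ``[200,300)`` are adjacent, not
    overlapping.
    """
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


@dataclass(frozen=True, slots=True)
class Peak:
    """A ChIP-seq peak with its fixed-size analysis window.

    ``window`` is centred on the midpoint of ``interval``; ``clipped`` marks
    windows that hit a chromosome boundary and were truncated.  Clipped peaks
    are excluded from sequence-scanning stages but kept for interval algebra.
    """

    id: str
    interval: GenomicInterval
    window: GenomicInterval
    clipped: bool = False


def make_window(
    interval: GenomicInterval,
    size: int = DEFAULT_WINDOW_SIZE,
    chrom_length: int | None = None,
) -> tuple[GenomicInterval, bool]:
    """Build the ``size`` bp window centred on ``interval``'s midpoint.

    Returns ``(window, clipped)``.  The window is ``[mid - size//2,
    mid - size//2 + size)``; if it extends past position 0 or past
    ``chrom_length`` it is clipped to the chromosome and flagged.
    """
    mid = interval.midpoint
    start = mid - size // 2
    end = start + size
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return GenomicInterval(interval.chrom, start, end), clipped


@dataclass(frozen=True, slots=True)
class TEInstance:
    """One annotated repeat copy (e.g. a single MIRb insertion)."""

    interval: GenomicInterval
    name: str
    te_class: str
    instance_id: str

    def __post_init__(self) -> None:
        if not self.name or not self.te_class:
            raise ValueError("TE name and class must be non-empty")


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """A gene reduced to its representative TSS."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")


@dataclass
class GenomeModel:
    """Chromosome lengths, optional sequences, and base composition.

    ``background`` is the (A, C, G, T) frequency vector used for PWM scoring
    and random-sequence generation; when built from sequences it is the
    empirical composition, strand-symmetrised (A=T, C=G averaged).
    """

    chrom_lengths: dict[str, int]
    sequences: dict[str, str] | None = None
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or np.any(self.background < 0):
            raise ValueError("background must be 4 nonnegative frequencies")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeModel":
        lengths = {c: len(s) for c, s in sequences.items()}
        bg = empirical_background(sequences, symmetrize=True)
        return cls(chrom_lengths=lengths, sequences=dict(sequences), background=bg)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def validate_feature(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self.chrom_lengths[interval.chrom]:
            raise ValueError(
                f"{interval} extends past chromosome end "
                f"{self.chrom_lengths[interval.chrom]}"
            )

    def fetch(self, interval: GenomicInterval) -> str:
        if self.sequences is None:
            raise ValueError("genome carries no sequences")
        return self.sequences[interval.chrom][interval.start:interval.end]


def empirical_background(
    sequences: Mapping[str, str], symmetrize: bool = True
) -> np.ndarray:
    """Empirical A/C/G/T frequencies of a genome (Ns ignored)."""
    counts = np.zeros(4, dtype=float)
    table = _base_code_table()
    for seq in sequences.values():
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        c = np.bincount(table[codes], minlength=5)[:4]
        counts += c
    if counts.sum() == 0:
        return np.full(4, 0.25)
    freqs = counts / counts.sum()
    if symmetrize:
        at = (freqs[0] + freqs[3]) / 2.0
        cg = (freqs[1] + freqs[2]) / 2.0
        freqs = np.array([at, cg, cg, at])
    return freqs


def _base_code_table() -> np.ndarray:
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table


# ---------------------------------------------------------------------------
# vectorised interval primitives
# ---------------------------------------------------------------------------

def any_overlap_flags(
    q_start: np.ndarray,
    q_end: np.ndarray,
    s_start: np.ndarray,
    s_end: np.ndarray,
) -> np.ndarray:
    """For each query span, does it overlap >=1 subject span? (same chrom).

    Subjects need not be sorted.  O((n+m) log m) via a sorted-start /
    prefix-max-end sweep; exact, cross-checked against the per-base oracle
    in the test suite.
    """
    if len(s_start) == 0:
        return np.zeros(len(q_start), dtype=bool)
    order = np.argsort(s_start, kind="stable")
    ss = np.asarray(s_start)[order]
    se = np.asarray(s_end)[order]
    prefix_max_end = np.maximum.accumulate(se)
    # subject overlaps query iff subject.start < q.end and subject.end > q.start
    j = np.searchsorted(ss, np.asarray(q_end), side="left")
    out = np.zeros(len(q_start), dtype=bool)
    nz = j > 0
    out[nz] = prefix_max_end[j[nz] - 1] > np.asarray(q_start)[nz]
    return out


def intervals_by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group intervals by chromosome into (starts, ends, original index)."""
    by: dict[str, list[int]] = {}
    for i, iv in enumerate(intervals):
        by.setdefault(iv.chrom, []).append(i)
    out = {}
    for chrom, idx in by.items():
        idx_arr = np.asarray(idx)
        out[chrom] = (
            np.asarray([intervals[i].start for i in idx]),
            np.asarray([intervals[i].end for i in idx]),
            idx_arr,
        )
    return out


# ---------------------------------------------------------------------------
# peak-set partition
# ---------------------------------------------------------------------------

@dataclass
class PeakSetPartition:
    """Two-set bookkeeping of peak windows: shared and set-specific peaks.

    ``a_and_b`` are the peaks of A whose window overlaps at least one window
    of B, and symmetrically for ``b_and_a``; the two shared counts generally
    differ because nearby peaks can intersect multiply.
    """

    a_and_b: list[Peak]
    b_and_a: list[Peak]
    a_only: list[Peak]
    b_only: list[Peak]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "A_and_B": len(self.a_and_b),
            "B_and_A": len(self.b_and_a),
            "A_only": len(self.a_only),
            "B_only": len(self.b_only),
        }


def _flag_overlapping(queries: Sequence[Peak], subjects: Sequence[Peak]) -> np.ndarray:
    flags = np.zeros(len(queries), dtype=bool)
    q_by = intervals_by_chrom([p.window for p in queries])
    s_by = intervals_by_chrom([p.window for p in subjects])
    for chrom, (qs, qe, qidx) in q_by.items():
        if chrom not in s_by:
            continue
        ss, se, _ = s_by[chrom]
        flags[qidx] = any_overlap_flags(qs, qe, ss, se)
    return flags


def partition_peaksets(
    a: Sequence[Peak], b: Sequence[Peak]
) -> PeakSetPartition:
    """Split two peak sets into shared / A-only / B-only, counted per side."""
    in_b = _flag_overlapping(a, b)
    in_a = _flag_overlapping(b, a)
    return PeakSetPartition(
        a_and_b=[p for p, f in zip(a, in_b) if f],
        b_and_a=[p for p, f in zip(b, in_a) if f],
        a_only=[p for p, f in zip(a, in_b) if not f],
        b_only=[p for p, f in zip(b, in_a) if not f],
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

@dataclass
class ParseReport:
    rows_read: int = 0
    rows_skipped: int = 0
    messages: list[str] = field(default_factory=list)

    def skip(self, msg: str) -> None:
        self.rows_skipped += 1
        self.messages.append(msg)
        logger.warning(msg)


def read_peaks(
    path: str | Path,
    dialect: str = "bed",
    window_size: int = DEFAULT_WINDOW_SIZE,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[list[Peak], ParseReport]:
    """Read a peak table (BED or a TSV export) into Peaks with windows.

    Columns: chrom, start, end[, id].  Rows with malformed coordinates are
    rejected and logged in the report; ids are auto-assigned ``peak_0001``…
    when the 4th column is absent.  Input order is preserved.
    """
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    report = ParseReport()
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if dialect == "tsv" else line.split()
            if len(fields) < 3:
                report.skip(f"{path.name}:{lineno}: fewer than 3 columns")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                report.skip(f"{path.name}:{lineno}: non-integer coordinates")
                continue
            if start >= end or start < 0:
                report.skip(
                    f"{path.name}:{lineno}: malformed coordinates "
                    f"[{start}, {end})"
                )
                continue
            report.rows_read += 1
            interval = GenomicInterval(fields[0], start, end)
            pid = (
                fields[3]
                if len(fields) >= 4 and fields[3].strip()
                else f"peak_{report.rows_read:04d}"
            )
            clen = chrom_lengths.get(interval.chrom) if chrom_lengths else None
            window, clipped = make_window(interval, window_size, clen)
            peaks.append(Peak(id=pid, interval=interval, window=window, clipped=clipped))
    if report.rows_read == 0:
        raise ValueError(f"{path}: no usable peak rows")
    return peaks, report


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path, what: str = "interval") -> None:
    """Write peak intervals (or windows) as BED4."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.window if what == "window" else p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\n")


def read_repeatmasker(
    path: str | Path, dialect: str = "rm_out"
) -> tuple[list[TEInstance], ParseReport]:
    """Read TE annotations from RepeatMasker ``.out`` or 5-column BED.

    rm_out coordinates (1-based inclusive) are converted to 0-based
    half-open; name (column 10) and class/family path (column 11) are kept
    verbatim.  The bed dialect expects chrom/start/end/name/class with an
    optional 6th strand column.
    """
    path = Path(path)
    report = ParseReport()
    tes: list[TEInstance] = []
    if dialect == "rm_out":
        with open(path) as fh:
            lines = fh.readlines()
        body = lines[3:]  # standard .out: two header lines + one blank
        for lineno, line in enumerate(body, 4):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 11:
                report.skip(f"{path.name}:{lineno}: too few columns for rm_out")
                continue
            chrom, begin, end = fields[4], int(fields[5]), int(fields[6])
            strand = "-" if fields[8] in ("C", "-") else "+"
            report.rows_read += 1
            tes.append(
                TEInstance(
                    interval=GenomicInterval(chrom, begin - 1, end, strand),
                    name=fields[9],
                    te_class=fields[10],
                    instance_id=f"te_{report.rows_read:06d}",
                )
            )
    elif dialect == "bed_name_class":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 5:
                    raise ValueError(
                        f"{path.name}:{lineno}: bed_name_class needs >=5 columns "
                        "(chrom start end name class)"
                    )
                strand = fields[5] if len(fields) >= 6 else "."
                report.rows_read += 1
                tes.append(
                    TEInstance(
                        interval=GenomicInterval(
                            fields[0], int(fields[1]), int(fields[2]), strand
                        ),
                        name=fields[3],
                        te_class=fields[4],
                        instance_id=f"te_{report.rows_read:06d}",
                    )
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return tes, report


def write_tes_bed(tes: Iterable[TEInstance], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tes:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.name}\t{t.te_class}"
                f"\t{iv.strand}\t{t.instance_id}\n"
            )


def read_tes_bed(path: str | Path) -> list[TEInstance]:
    """Round-trip reader for :func:`write_tes_bed` output (BED5+)."""
    tes, _ = read_repeatmasker(path, dialect="bed_name_class")
    # restore stored instance ids if present as 7th column
    out = []
    with open(path) as fh:
        rows = [l.split() for l in fh if l.strip() and not l.startswith("#")]
    for te, row in zip(tes, rows):
        if len(row) >= 7:
            te = replace(te, instance_id=row[6])
        out.append(te)
    return out


def read_genes(path: str | Path) -> tuple[list[GeneAnnotation], ParseReport]:
    """Read genes from a 4-column TSV: gene_id, chrom, tss, strand."""
    report = ParseReport()
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                report.skip(f"line {lineno}: need gene_id chrom tss strand")
                continue
            report.rows_read += 1
            genes.append(
                GeneAnnotation(
                    gene_id=fields[0],
                    chrom=fields[1],
                    tss=int(fields[2]),
                    strand=fields[3],
                )
            )
    return genes, report


def write_genes(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, length = line.split()[:2]
            sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(chrom_lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_genome_fasta(path: str | Path) -> GenomeModel:
    from Bio import SeqIO

    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    return GenomeModel.from_sequences(sequences)


def write_genome_fasta(genome: GenomeModel, path: str | Path, width: int = 80) -> None:
    if genome.sequences is None:
        raise ValueError("genome carries no sequences")
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pwms(path: str | Path, format: str = "jaspar", pseudocount: float = 0.25):
    """Read PWMs from JASPAR or TRANSFAC flat text via Bio.motifs.

    Count matrices are normalised to per-position probabilities with the
    configured pseudocount (added per base before normalisation).  Returns a
    list of :class:`te_exapt.tfbs_affinity.PWM`.
    """
    from Bio import motifs as bio_motifs

    from .tfbs_affinity import PWM

    fmt = format.lower()
    if fmt not in ("jaspar", "transfac"):
        raise ValueError(f"unknown PWM format {format!r}")
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar" if fmt == "jaspar" else "TRANSFAC")
    pwms = []
    for m in parsed:
        mid = getattr(m, "matrix_id", None) or m.name or f"pwm_{len(pwms)+1}"
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)  # (4, w)
        col_tot = counts.sum(axis=0)
        if np.any(col_tot <= 0):
            pos = int(np.argmax(col_tot <= 0))
            raise ValueError(
                f"matrix {mid}: position {pos} does not sum to a positive total"
            )
        pwms.append(PWM.from_counts(mid, counts, pseudocount=pseudocount))
    return pwms
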