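"""PWM scoring, threshold calibration and the Transposon Affinity Score.

A PWM is stored as per-position base probabilities (pseudocounted counts,
0.25 per base by default) and scored against a background composition as a
log2 likelihood ratio summed over positions; ``N`` bases contribute 0.
Scanning covers both strands of a fixed 200 bp window centred on each peak.

Per-TF score thresholds are calibrated by Monte Carlo so that the
probability that a *random* background window of the scanning size contains
at least one hit equals a target rate (0.01 by default) — i.e. the TAS of a
random sequence is the target.  The Transposon Affinity Score of a TE
family for a TF is then the fraction of the family's peak-overlapping
instances that carry at least one hit whose matched bases intersect the
instance's span.  Families in which some TF reaches a TAS of at least 0.10
(ten times the chance level) flag that TF as a putative interactor, and the
full TE x TF matrix is reported with average-linkage cluster orders for
both axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_model import GenomicInterval, Peak, TEInstance, intervals_by_chrom

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to codes A=0, C=1, G=2, T=3, other=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def reverse_complement(seq: str) -> str:
    return decode_sequence(_COMPLEMENT[encode_sequence(seq)][::-1])


@dataclass
class CalibrationReport:
    target_rate: float
    achieved_rate: float
    n_mc: int
    window: int
    seed: int | None


@dataclass
class PWM:
    """Position weight matrix with background model and calibrated threshold.

    ``probs`` has shape (4, width), rows in A, C, G, T order; each column
    sums to 1.  ``threshold`` is a log2-odds score; it is unset until
    :func:`calibrate_threshold` has run.
    """

    id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25
    threshold: float | None = None
    calibration: CalibrationReport | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError(f"PWM {self.id}: probs must be (4, width>=1)")
        if np.any(np.abs(self.probs.sum(axis=0) - 1.0) > 1e-9):
            raise ValueError(f"PWM {self.id}: position probabilities must sum to 1")
        if self.threshold is not None and not np.isfinite(self.threshold):
            raise ValueError(f"PWM {self.id}: threshold must be finite")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(
        cls,
        id: str,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        background: np.ndarray | None = None,
    ) -> "PWM":
        """Normalise a (4, width) count matrix with a per-base pseudocount."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be (4, width)")
        padded = counts + pseudocount
        probs = padded / padded.sum(axis=0, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(id=id, probs=probs, background=bg, pseudocount=pseudocount)

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """(5, width) log2-odds lookup; 5th row (N / unknown) scores 0."""
        bg = self.background if background is None else np.asarray(background, float)
        lo = np.log2(self.probs / bg[:, None])
        return np.vstack([lo, np.zeros((1, self.width))])

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background)[:4].max(axis=0).sum())

    def consensus_word(self) -> str:
        """The maximum-probability word (ties broken toward A<C<G<T)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def with_background(self, background: np.ndarray) -> "PWM":
        return replace(self, background=np.asarray(background, float))


@dataclass(frozen=True, slots=True)
class MotifHit:
    peak_id: str
    position: int  # window-relative, 0-based start of the matched word
    abs_position: int  # genome coordinate of the matched word start
    strand: str
    score: float
    pwm_id: str


@dataclass(frozen=True, slots=True)
class TASRecord:
    """Fraction of a family's peak-overlapping instances carrying a TF."""

    te_name: str
    tf_id: str
    n_instances: int
    n_carrying: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_carrying <= self.n_instances):
            raise ValueError("need 0 <= n_carrying <= n_instances")

    @property
    def tas(self) -> float:
        return self.n_carrying / self.n_instances


# ---------------------------------------------------------------------------
# scoring and scanning
# ---------------------------------------------------------------------------

def score_word(pwm: PWM, word: str, strand: str = "+") -> float:
    """Log2-odds score of one word; reverse strand scores the reverse
    complement.  N contributes 0 at its position."""
    if len(word) != pwm.width:
        raise ValueError(f"word length {len(word)} != PWM width {pwm.width}")
    codes = encode_sequence(word)
    if strand == "-":
        codes = _COMPLEMENT[codes][::-1]
    lo = pwm.log_odds()
    return float(lo[codes, np.arange(pwm.width)].sum())


def _position_scores(codes: np.ndarray, lo: np.ndarray, width: int) -> np.ndarray:
    """Scores of every length-``width`` word start in ``codes`` (1-D or 2-D).

    For 2-D input (n_sequences, seq_len) returns (n_sequences, n_positions).
    """
    L = codes.shape[-1]
    n_pos = L - width + 1
    if n_pos <= 0:
        return np.zeros(codes.shape[:-1] + (0,))
    out = np.zeros(codes.shape[:-1] + (n_pos,))
    for j in range(width):
        out += lo[codes[..., j : j + n_pos], j]
    return out


def _rc_log_odds(lo: np.ndarray) -> np.ndarray:
    """Log-odds of the reverse-complement motif on the forward sequence."""
    return lo[_COMPLEMENT][:, ::-1]


def scan_sequence(
    seq: str, pwm: PWM, threshold: float | None = None
) -> list[tuple[int, str, float]]:
    """All matches of ``pwm`` on both strands with score >= threshold.

    Returns (position, strand, score) sorted by position then strand; a
    reverse-strand hit at position p matches the reverse complement of
    ``seq[p:p+width]``.  Sequences shorter than the motif yield no hits.
    """
    t = pwm.threshold if threshold is None else threshold
    if t is None:
        raise ValueError(f"PWM {pwm.id}: no threshold set; calibrate first")
    codes = encode_sequence(seq)
    if len(codes) < pwm.width:
        logger.info("sequence shorter than PWM %s width; empty scan", pwm.id)
        return []
    lo = pwm.log_odds()
    hits = []
    for strand, mat in (("+", lo), ("-", _rc_log_odds(lo))):
        scores = _position_scores(codes, mat, pwm.width)
        for pos in np.nonzero(scores >= t)[0]:
            hits.append((int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def scan_window(peak: Peak, sequence: str, pwm: PWM) -> list[MotifHit]:
    """Scan one peak window (sequence given in window coordinates)."""
    return [
        MotifHit(
            peak_id=peak.id,
            position=pos,
            abs_position=peak.window.start + pos,
            strand=strand,
            score=score,
            pwm_id=pwm.id,
        )
        for pos, strand, score in scan_sequence(sequence, pwm)
    ]


def scan_peaks(
    peaks: Sequence[Peak], sequences: Mapping[str, str], pwm: PWM
) -> list[MotifHit]:
    """Scan every scannable (non-clipped) peak window against one PWM."""
    hits: list[MotifHit] = []
    for p in peaks:
        if p.clipped:
            continue
        seq = sequences[p.window.chrom][p.window.start : p.window.end]
        hits.extend(scan_window(p, seq, pwm))
    return hits


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def random_sequence_codes(
    n: int, length: int, background: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n, length) i.i.d. base codes at the background composition."""
    bg = np.asarray(background, float)
    cum = np.cumsum(bg / bg.sum())
    u = rng.random((n, length))
    return np.searchsorted(cum, u, side="right").astype(np.uint8)


def window_max_scores(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Per-sequence maximum log-odds score over all positions and strands."""
    lo = pwm.log_odds()
    fwd = _position_scores(codes, lo, pwm.width)
    rev = _position_scores(codes, _rc_log_odds(lo), pwm.width)
    if fwd.shape[-1] == 0:
        return np.full(codes.shape[0], -np.inf)
    return np.maximum(fwd.max(axis=-1), rev.max(axis=-1))


def calibrate_threshold(
    pwm: PWM,
    background: np.ndarray | None = None,
    target_rate: float = 0.01,
    window: int = 200,
    n_mc: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PWM:
    """Set the score threshold so a random window carries a hit at the target rate.

    Monte Carlo: draw ``n_mc`` i.i.d. background windows, take each window's
    maximum score over positions and strands, and set the threshold at the
    empirical (1 − target_rate) quantile of those maxima, so that exactly
    ``round(target_rate * n_mc)`` calibration windows contain >= 1 hit.
    Returns a new PWM with ``threshold`` and a :class:`CalibrationReport`.
    """
    if not (0 < target_rate < 1):
        raise ValueError("target_rate must be in (0, 1)")
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for a stable quantile")
    bg = pwm.background if background is None else np.asarray(background, float)
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = random_sequence_codes(n_mc, window, bg, rng)
    pwm_bg = pwm.with_background(bg)
    maxima = np.sort(window_max_scores(codes, pwm_bg))
    k = max(1, int(round(target_rate * n_mc)))
    t = float(maxima[n_mc - k])
    achieved = float(np.mean(maxima >= t))
    if achieved > 10 * target_rate or achieved > 0.5:
        raise ValueError(
            f"PWM {pwm.id}: degenerate score distribution; cannot reach the "
            f"target rate {target_rate} (achieved {achieved:.3f})"
        )
    report = CalibrationReport(
        target_rate=target_rate,
        achieved_rate=achieved,
        n_mc=n_mc,
        window=window,
        seed=seed,
    )
    return replace(pwm_bg, threshold=t, calibration=report)


def hit_rate(
    pwm: PWM,
    n: int,
    window: int = 200,
    background: np.ndarray | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    threshold: float | None = None,
) -> float:
    """Fraction of ``n`` fresh random windows containing >= 1 hit."""
    bg = pwm.background if background is None else np.asarray(background, float)
    if rng is None:
        rng = np.random.default_rng(seed)
    t = pwm.threshold if threshold is None else threshold
    if t is None:
        raise ValueError(f"PWM {pwm.id}: no threshold")
    codes = random_sequence_codes(n, window, bg, rng)
    maxima = window_max_scores(codes, pwm.with_background(bg))
    return float(np.mean(maxima >= t))


# ---------------------------------------------------------------------------
# Transposon Affinity Score
# ---------------------------------------------------------------------------

def _window_instance_pairs(
    peaks: Sequence[Peak], tes: Sequence[TEInstance]
) -> dict[int, list[int]]:
    """Map TE index -> indices of peaks whose window overlaps it."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for pi, p in enumerate(peaks):
        trees.setdefault(p.window.chrom, IntervalTree()).addi(
            p.window.start, p.window.end, pi
        )
    pairs: dict[int, list[int]] = {}
    for ti, te in enumerate(tes):
        tree = trees.get(te.interval.chrom)
        if tree is None:
            continue
        found = tree.overlap(te.interval.start, te.interval.end)
        if found:
            pairs[ti] = sorted(iv.data for iv in found)
    return pairs


def compute_tas(
    peaks: Sequence[Peak],
    tes: Sequence[TEInstance],
    sequences: Mapping[str, str],
    pwms: Sequence[PWM] | PWM,
    carrying: str = "span",
) -> list[TASRecord]:
    """TAS of every TE family for every given (calibrated) PWM.

    The instance set of family f is the set of distinct instances whose span
    overlaps >= 1 peak window.  With ``carrying="span"`` (default) an
    instance carries a TF iff some hit in an overlapping window has its
    matched bases intersecting the instance's span; ``carrying="window"``
    relaxes this to any hit anywhere in an overlapping window.  Families
    with no instances in peaks are omitted.
    """
    if carrying not in ("span", "window"):
        raise ValueError("carrying must be 'span' or 'window'")
    pwm_list = [pwms] if isinstance(pwms, PWM) else list(pwms)
    for pwm in pwm_list:
        if pwm.threshold is None:
            raise ValueError(f"PWM {pwm.id}: calibrate before computing TAS")
    scannable = [p for p in peaks if not p.clipped]
    pairs = _window_instance_pairs(scannable, tes)

    # scan each involved window once per PWM
    involved = sorted({pi for plist in pairs.values() for pi in plist})
    hits_by_peak: dict[str, dict[int, list[MotifHit]]] = {
        pwm.id: {} for pwm in pwm_list
    }
    for pi in involved:
        p = scannable[pi]
        seq = sequences[p.window.chrom][p.window.start : p.window.end]
        for pwm in pwm_list:
            hits_by_peak[pwm.id][pi] = scan_window(p, seq, pwm)

    records: list[TASRecord] = []
    families = sorted({tes[ti].name for ti in pairs})
    for pwm in pwm_list:
        for fam in families:
            members = [ti for ti in pairs if tes[ti].name == fam]
            n_carrying = 0
            for ti in members:
                te = tes[ti]
                carried = False
                for pi in pairs[ti]:
                    for hit in hits_by_peak[pwm.id][pi]:
                        if carrying == "window" or (
                            hit.abs_position < te.interval.end
                            and hit.abs_position + pwm.width > te.interval.start
                        ):
                            carried = True
                            break
                    if carried:
                        break
                n_carrying += carried
            records.append(
                TASRecord(
                    te_name=fam,
                    tf_id=pwm.id,
                    n_instances=len(members),
                    n_carrying=n_carrying,
                )
            )
    return records


@dataclass
class TASMatrix:
    """Dense TE x TF matrix of TAS values with cluster leaf orders."""

    matrix: "object"  # pandas.DataFrame, families x TFs
    interactors: list[str]
    row_order: list[str]
    col_order: list[str]
    tas_min: float


def tas_matrix(records: Iterable[TASRecord], tas_min: float = 0.10) -> TASMatrix:
    """Assemble the TE x TF affinity matrix and the putative-interactor list.

    Missing (family, TF) cells are 0.  A TF is a putative interactor when
    its TAS reaches ``tas_min`` (inclusive) in at least one family.  Row and
    column orders come from average-linkage hierarchical clustering on
    Euclidean distance, with name-sorted input for deterministic ties.
    """
    import pandas as pd
    from scipy.cluster.hierarchy import leaves_list, linkage

    recs = sorted(records, key=lambda r: (r.te_name, r.tf_id))
    if not recs:
        raise ValueError("no TAS records")
    families = sorted({r.te_name for r in recs})
    tfs = sorted({r.tf_id for r in recs})
    mat = pd.DataFrame(0.0, index=families, columns=tfs)
    for r in recs:
        mat.loc[r.te_name, r.tf_id] = r.tas
    interactors = [tf for tf in tfs if (mat[tf] >= tas_min).any()]

    def _leaf_order(values: np.ndarray, labels: list[str]) -> list[str]:
        if len(labels) < 2:
            return list(labels)
        z = linkage(values, method="average", metric="euclidean")
        return [labels[i] for i in leaves_list(z)]

    row_order = _leaf_order(mat.values, families)
    col_order = _leaf_order(mat.values.T, tfs)
    return TASMatrix(
        matrix=mat,
        interactors=interactors,
        row_order=row_order,
        col_order=col_order,
        tas_min=tas_min,
    )
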