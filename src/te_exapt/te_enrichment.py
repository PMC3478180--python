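"""TE-family enrichment z-scores against locally matched random peak sets.

The statistic: count, per TE family (and per class), the number of distinct
repeat instances overlapped by the 200 bp peak windows; rebuild the peak
set ``n_random`` times by redrawing each peak uniformly within the 1 Mb
genomic window that contains it (so local density is matched); and report

    z = (x − μ) / √s

with μ and s the sample mean and (unbiased) variance of the count over the
random sets.  Families with z above 3 are called enriched.  Counting is at
the level of distinct TE instances — an instance overlapping two windows
counts once, a window overlapping two instances increments both — with an
optional per-peak counting mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_model import (
    GenomeModel,
    GenomicInterval,
    Peak,
    TEInstance,
    any_overlap_flags,
)

logger = logging.getLogger(__name__)

DEFAULT_N_RANDOM = 1000
DEFAULT_LOCAL_WINDOW = 1_000_000
Z_MIN_DEFAULT = 3.0


@dataclass
class EnrichmentResult:
    """Observed count, resampled mean/variance and z for one family or class."""

    unit: str
    level: str  # "family" | "class"
    x: int
    mu: float
    var: float
    z: float
    n_random: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.var < 0:
            raise ValueError("variance must be >= 0")


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass
class _TEIndex:
    """Arrays over TE instances, grouped per chromosome, for fast counting."""

    families: list[str]
    classes: list[str]  # te_class of each family, aligned with `families`
    fam_of_class: dict[str, list[int]]
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # start, end, fam code
    n_instances: int


def _build_te_index(tes: Sequence[TEInstance]) -> _TEIndex:
    families = sorted({t.name for t in tes})
    fam_code = {f: i for i, f in enumerate(families)}
    class_of: dict[str, str] = {}
    for t in tes:
        prev = class_of.setdefault(t.name, t.te_class)
        if prev != t.te_class:
            raise ValueError(f"family {t.name} maps to multiple classes")
    classes = [class_of[f] for f in families]
    fam_of_class: dict[str, list[int]] = {}
    for i, c in enumerate(classes):
        fam_of_class.setdefault(c, []).append(i)
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    by: dict[str, list[TEInstance]] = {}
    for t in tes:
        by.setdefault(t.interval.chrom, []).append(t)
    for chrom, group in by.items():
        per_chrom[chrom] = (
            np.array([t.interval.start for t in group]),
            np.array([t.interval.end for t in group]),
            np.array([fam_code[t.name] for t in group]),
        )
    return _TEIndex(families, classes, fam_of_class, per_chrom, len(tes))


def _windows_by_chrom(peaks: Sequence[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by.setdefault(p.window.chrom, []).append(p.window)
    return {
        c: (np.array([w.start for w in ws]), np.array([w.end for w in ws]))
        for c, ws in by.items()
    }


def _family_count_vector(
    index: _TEIndex, windows: dict[str, tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Distinct-instance counts per family code against a window set."""
    counts = np.zeros(len(index.families), dtype=np.int64)
    for chrom, (ts, te, fam) in index.per_chrom.items():
        if chrom not in windows:
            continue
        ws, we = windows[chrom]
        hit = any_overlap_flags(ts, te, ws, we)
        if hit.any():
            counts += np.bincount(fam[hit], minlength=len(index.families))
    return counts


def _per_peak_count_vector(
    index: _TEIndex, windows: dict[str, tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Per-peak counts: number of windows overlapping >=1 instance of f."""
    counts = np.zeros(len(index.families), dtype=np.int64)
    for chrom, (ts, te, fam) in index.per_chrom.items():
        if chrom not in windows:
            continue
        ws, we = windows[chrom]
        for code in np.unique(fam):
            sel = fam == code
            hit = any_overlap_flags(ws, we, ts[sel], te[sel])
            counts[code] += int(hit.sum())
    return counts


def count_te_overlaps(
    peaks: Sequence[Peak],
    tes: Sequence[TEInstance],
    unit: str = "instance",
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-family and per-class overlap counts of TEs with peak windows.

    ``unit="instance"`` (default) counts distinct TE instances overlapped by
    at least one window; ``unit="peak"`` counts windows overlapping at least
    one instance of the family.  Class counts aggregate family counts.
    """
    index = _build_te_index(tes)
    windows = _windows_by_chrom(peaks)
    if unit == "instance":
        vec = _family_count_vector(index, windows)
    elif unit == "peak":
        vec = _per_peak_count_vector(index, windows)
    else:
        raise ValueError("unit must be 'instance' or 'peak'")
    fam_counts = {f: int(c) for f, c in zip(index.families, vec)}
    class_counts = {
        c: int(vec[idx].sum()) for c, idx in index.fam_of_class.items()
    }
    return fam_counts, class_counts


# ---------------------------------------------------------------------------
# locally matched resampling
# ---------------------------------------------------------------------------

def _sample_starts(
    peaks: Sequence[Peak],
    genome: GenomeModel,
    rng: np.random.Generator,
    local_window: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Random window starts, one per real peak, within its 1 Mb window."""
    out: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        w = p.window
        length = w.length
        chrom_len = genome.chrom_lengths[w.chrom]
        widx = w.midpoint // local_window
        w_start = widx * local_window
        w_end = min((widx + 1) * local_window, chrom_len)
        if w_end - w_start < length:
            logger.info(
                "local window shorter than peak length on %s; using whole chromosome",
                w.chrom,
            )
            w_start, w_end = 0, chrom_len
        start = int(rng.integers(w_start, w_end - length + 1))
        out.setdefault(w.chrom, []).append((start, start + length))
    return {
        c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
        for c, v in out.items()
    }


def sample_random_peakset(
    peaks: Sequence[Peak],
    genome: GenomeModel,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    local_window: int = DEFAULT_LOCAL_WINDOW,
) -> list[Peak]:
    """One matched random peak per real peak: same length, same 1 Mb window.

    Each chromosome is divided into fixed 1 Mb windows anchored at 0; a peak
    belongs to the window containing its midpoint; the random counterpart's
    start is drawn uniformly so the whole random window stays inside that
    1 Mb window (the final partial window of a chromosome is used as-is).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    starts = _sample_starts(peaks, genome, rng, local_window)
    # rebuild in input order
    cursors = {c: 0 for c in starts}
    out = []
    for i, p in enumerate(peaks):
        c = p.window.chrom
        s = int(starts[c][0][cursors[c]])
        e = int(starts[c][1][cursors[c]])
        cursors[c] += 1
        iv = GenomicInterval(c, s, e)
        out.append(Peak(id=f"rand_{i:05d}", interval=iv, window=iv))
    return out


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRun:
    """Full output of one resampling run (results plus audit trail)."""

    results: list[EnrichmentResult]
    replicate_seeds: list[int]
    n_random: int
    unit: str
    replicate_counts: np.ndarray | None = None  # (n_random, n_families)
    families: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def by_unit(self, unit: str) -> EnrichmentResult:
        for r in self.results:
            if r.unit == unit:
                return r
        raise KeyError(unit)


def _zscore(x: float, mu: float, var: float) -> tuple[float, bool]:
    if var > 0:
        return (x - mu) / math.sqrt(var), False
    if x == mu:
        return 0.0, True
    return math.copysign(math.inf, x - mu), True


def enrichment_zscores(
    peaks: Sequence[Peak],
    tes: Sequence[TEInstance],
    genome: GenomeModel,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int | None = None,
    unit: str = "instance",
    local_window: int = DEFAULT_LOCAL_WINDOW,
    keep_replicates: bool = False,
) -> EnrichmentRun:
    """Family- and class-level enrichment z-scores by local resampling.

    A master seed spawns one child generator per replicate (child seeds are
    recorded for exact reruns).  μ and s are the sample mean and unbiased
    variance of the counts over the ``n_random`` random peak sets; a zero
    variance flags the result degenerate (z = 0 when x equals μ, signed
    infinity otherwise).
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    index = _build_te_index(tes)
    windows = _windows_by_chrom(peaks)
    count_fn = (
        _family_count_vector if unit == "instance" else _per_peak_count_vector
    )
    if unit not in ("instance", "peak"):
        raise ValueError("unit must be 'instance' or 'peak'")
    x_fam = count_fn(index, windows)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_random)
    replicate_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    counts = np.empty((n_random, len(index.families)), dtype=np.int64)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        rand_windows = _sample_starts(peaks, genome, rng, local_window)
        counts[r] = count_fn(index, rand_windows)

    results: list[EnrichmentResult] = []

    def _emit(name: str, level: str, x: int, col: np.ndarray) -> None:
        mu = float(col.mean())
        var = float(col.var(ddof=1))
        if x == 0 and mu == 0.0 and var == 0.0:
            return  # never observed anywhere: omitted
        z, degenerate = _zscore(x, mu, var)
        results.append(
            EnrichmentResult(
                unit=name, level=level, x=int(x), mu=mu, var=var, z=z,
                n_random=n_random, degenerate=degenerate,
            )
        )

    for i, fam in enumerate(index.families):
        _emit(fam, "family", int(x_fam[i]), counts[:, i])
    for cls, idx in sorted(index.fam_of_class.items()):
        _emit(
            cls, "class", int(x_fam[idx].sum()), counts[:, idx].sum(axis=1)
        )
    return EnrichmentRun(
        results=results,
        replicate_seeds=replicate_seeds,
        n_random=n_random,
        unit=unit,
        replicate_counts=counts if keep_replicates else None,
        families=index.families,
    )


def filter_enriched(
    results: Iterable[EnrichmentResult],
    z_min: float = Z_MIN_DEFAULT,
    level: str | None = None,
) -> list[EnrichmentResult]:
    """Results with z strictly above ``z_min``, sorted descending by z."""
    kept = [
        r
        for r in results
        if r.z > z_min and (level is None or r.level == level)
    ]
    return sorted(kept, key=lambda r: (-r.z, r.unit))


def write_enrichment_tsv(
    run: EnrichmentRun, path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_random={run.n_random} unit={run.unit}\n")
        fh.write(f"# replicate_seeds={','.join(map(str, run.replicate_seeds))}\n")
        fh.write("#unit\tlevel\tx\tmu\tvar\tz\tn_random\tdegenerate\n")
        for r in run.results:
            fh.write(
                f"{r.unit}\t{r.level}\t{r.x}\t{r.mu:.4f}\t{r.var:.4f}"
                f"\t{r.z:.4f}\t{r.n_random}\t{int(r.degenerate)}\n"
            )
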