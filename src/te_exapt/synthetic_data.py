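"""Synthetic genomes with planted TE families, peaks, motifs and synteny.

Everything downstream of raw data — family enrichment z-scores, TAS
calibration, spacing correlators, TSS association, conserved-TE recovery —
is exercised here against a genome whose ground truth is known exactly:

* i.i.d. background sequence at a configured GC content (defaults to a
  mammalian-like 0.41);
* TE families planted as decayed consensus copies (i.i.d. substitutions at
  a per-base divergence rate, no indels), optionally carrying motif words
  or motif *pairs* at a fixed start-to-start spacing inside the consensus
  (emulating a conserved core such as the ~70 bp MIR core);
* a peak set whose expected per-family overlap rate is a controlled
  multiple k of the background rate b_f (k = 1 for every family is the
  exact null: peaks are then placed uniformly);
* TSSs placed near a configured fraction of planted TEs;
* a second genome produced by cutting the first into syntenic blocks,
  shuffling and partially inverting them, with a configured fraction of TE
  instances conserved through the map.

Every generator is a pure function of (config, seed): reruns are
bit-identical.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_left, insort
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_model import (
    DEFAULT_WINDOW_SIZE,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    Peak,
    TEInstance,
    empirical_background,
    write_chrom_sizes,
    write_genes,
    write_genome_fasta,
    write_peaks_bed,
    write_tes_bed,
)
from .synteny_conservation import SyntenyBlock, project_interval, write_blocks_tsv
from .tfbs_affinity import PWM, decode_sequence, encode_sequence

logger = logging.getLogger(__name__)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TEFamilySpec:
    name: str
    te_class: str
    consensus_length: int
    copy_number: int
    divergence: float

    def __post_init__(self) -> None:
        if self.copy_number < 0 or self.consensus_length < 1:
            raise ValueError("counts must be >= 0 and length >= 1")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")


@dataclass(frozen=True)
class PWMSpec:
    id: str
    width: int


@dataclass(frozen=True)
class PlantedMotif:
    pwm_id: str
    family: str
    offset: int  # within the family consensus


@dataclass(frozen=True)
class PlantedSpacing:
    pwm_a: str
    pwm_b: str
    family: str
    offset_a: int
    distance: int  # start-to-start, B minus A


@dataclass(frozen=True)
class SyntenySpec:
    n_blocks: int = 10
    inversion_fraction: float = 0.5
    conserved_te_fraction: float = 0.4
    n_decoys: int = 20

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        for f in (self.inversion_fraction, self.conserved_te_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class SimulationConfig:
    """All knobs of the simulated study, with the study's defaults.

    Defaults describe the standing test-bed: a 2 x 5 Mb genome, 50 TE
    families of 200 copies x 150 bp at 10% divergence (~15% TE content,
    giving per-family background window-overlap rates b_f ~ 0.007), 2,000
    ChIP-seq-like 200 bp peaks, and a panel of sharp fixture PWMs of widths
    8-15.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    gc_content: float = 0.41
    te_families: list[TEFamilySpec] = field(
        default_factory=lambda: default_te_families()
    )
    pwm_specs: list[PWMSpec] = field(default_factory=lambda: default_pwm_specs())
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    planted_spacings: list[PlantedSpacing] = field(default_factory=list)
    n_peaks: int = 2000
    window_size: int = DEFAULT_WINDOW_SIZE
    enrichment_multipliers: dict[str, float] = field(default_factory=dict)
    n_genes: int = 500
    tss_near_te_fraction: float = 0.3
    tss_near_distance: int = 2000
    synteny: SyntenySpec | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        if not (0.0 <= self.tss_near_te_fraction <= 1.0):
            raise ValueError("tss_near_te_fraction must be in [0, 1]")
        if self.n_peaks < 0 or self.n_genes < 0:
            raise ValueError("counts must be >= 0")
        for fam, k in self.enrichment_multipliers.items():
            if k < 0:
                raise ValueError(f"multiplier for {fam} must be >= 0")
        for sp in self.planted_spacings:
            if sp.distance < 0 or sp.distance >= self.window_size:
                raise ValueError("planted spacing must satisfy 0 <= d < window size")


_DEFAULT_CLASSES = ["SINE/MIR", "LTR/ERV1", "LTR/MaLR", "DNA/hAT-Charlie", "LINE/L2"]


def default_te_families(
    n_families: int = 50,
    consensus_length: int = 150,
    copy_number: int = 200,
    divergence: float = 0.10,
) -> list[TEFamilySpec]:
    return [
        TEFamilySpec(
            name=f"FAM{i:02d}",
            te_class=_DEFAULT_CLASSES[i % len(_DEFAULT_CLASSES)],
            consensus_length=consensus_length,
            copy_number=copy_number,
            divergence=divergence,
        )
        for i in range(n_families)
    ]


def default_pwm_specs() -> list[PWMSpec]:
    return [PWMSpec(id=f"TF_W{w:02d}", width=w) for w in range(8, 16)]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedMotifSite:
    pwm_id: str
    family: str
    instance_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class PlantedSpacingSite:
    pwm_a: str
    pwm_b: str
    instance_id: str
    start_a: int  # genome-absolute
    start_b: int
    distance: int


@dataclass
class GroundTruth:
    family_multipliers: dict[str, float] = field(default_factory=dict)
    background_overlap: dict[str, float] = field(default_factory=dict)
    te_instances: list[TEInstance] = field(default_factory=list)
    planted_motif_sites: list[PlantedMotifSite] = field(default_factory=list)
    planted_spacing_sites: list[PlantedSpacingSite] = field(default_factory=list)
    peak_families: dict[str, str | None] = field(default_factory=dict)
    gene_te: dict[str, str | None] = field(default_factory=dict)
    conserved_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: GenomeModel
    tes: list[TEInstance]
    peaks: list[Peak]
    genes: list[GeneAnnotation]
    pwms: list[PWM]
    consensus: dict[str, str]
    truth: GroundTruth
    genome_b: GenomeModel | None = None
    tes_b: list[TEInstance] | None = None
    blocks: list[SyntenyBlock] | None = None


# ---------------------------------------------------------------------------
# genome and PWMs
# ---------------------------------------------------------------------------

def _background_from_gc(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def _random_codes(n: int, background: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(background / background.sum())
    return np.searchsorted(cum, rng.random(n), side="right").astype(np.uint8)


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenomeModel:
    """i.i.d. background genome at the configured GC content."""
    if not config.chrom_lengths:
        raise ValueError("chrom_lengths must be non-empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    bg = _background_from_gc(config.gc_content)
    sequences = {
        chrom: decode_sequence(_random_codes(length, bg, rng))
        for chrom, length in config.chrom_lengths.items()
    }
    return GenomeModel.from_sequences(sequences)


def generate_pwms(
    specs: Sequence[PWMSpec],
    rng: np.random.Generator,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Sharp fixture PWMs: one dominant base per position.

    Dominant counts vary position to position (12-24 vs 0-2 for the rest),
    so word scores are close to continuous and threshold quantiles have no
    heavy ties.
    """
    pwms = []
    for spec in specs:
        dominant = rng.integers(0, 4, size=spec.width)
        counts = rng.integers(0, 3, size=(4, spec.width)).astype(float)
        counts[dominant, np.arange(spec.width)] = rng.integers(12, 25, size=spec.width)
        pwm = PWM.from_counts(spec.id, counts, pseudocount=0.25, background=background)
        pwms.append(pwm)
    return pwms


# ---------------------------------------------------------------------------
# consensus construction and motif planting
# ---------------------------------------------------------------------------

def plant_motif_combination(
    consensus: str,
    pwm_a: PWM,
    pwm_b: PWM,
    offset_a: int,
    distance: int,
    allow_overlap: bool = False,
) -> str:
    """Embed the two PWMs' maximum-probability words at start-to-start
    distance ``distance`` (B after A) in a consensus sequence."""
    if offset_a < 0 or offset_a + distance + pwm_b.width > len(consensus):
        raise ValueError("planted sites must fit inside the consensus")
    if distance < pwm_a.width and not allow_overlap:
        raise ValueError(
            f"sites overlap at distance {distance} < width {pwm_a.width}; "
            "pass allow_overlap=True to permit"
        )
    word_a, word_b = pwm_a.consensus_word(), pwm_b.consensus_word()
    seq = list(consensus)
    seq[offset_a : offset_a + pwm_a.width] = word_a
    start_b = offset_a + distance
    seq[start_b : start_b + pwm_b.width] = word_b
    return "".join(seq)


def plant_motif(consensus: str, pwm: PWM, offset: int) -> str:
    if offset < 0 or offset + pwm.width > len(consensus):
        raise ValueError("planted site must fit inside the consensus")
    seq = list(consensus)
    seq[offset : offset + pwm.width] = pwm.consensus_word()
    return "".join(seq)


def build_family_consensus(
    config: SimulationConfig,
    pwms: Mapping[str, PWM],
    rng: np.random.Generator,
    background: np.ndarray,
) -> dict[str, str]:
    """Random consensus per family with the configured motifs planted."""
    consensus = {
        fam.name: decode_sequence(_random_codes(fam.consensus_length, background, rng))
        for fam in config.te_families
    }
    for pm in config.planted_motifs:
        consensus[pm.family] = plant_motif(
            consensus[pm.family], pwms[pm.pwm_id], pm.offset
        )
    for sp in config.planted_spacings:
        consensus[sp.family] = plant_motif_combination(
            consensus[sp.family],
            pwms[sp.pwm_a],
            pwms[sp.pwm_b],
            sp.offset_a,
            sp.distance,
        )
    return consensus


# ---------------------------------------------------------------------------
# TE planting
# ---------------------------------------------------------------------------

class _Occupancy:
    """Per-chromosome registry of planted spans for overlap-free placement."""

    def __init__(self) -> None:
        self._spans: dict[str, list[tuple[int, int]]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        spans = self._spans.get(chrom, [])
        i = bisect_left(spans, (start, start))
        if i < len(spans) and spans[i][0] < end:
            return False
        if i > 0 and spans[i - 1][1] > start:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._spans.setdefault(chrom, []), (start, end))


def _mutate_copy(
    codes: np.ndarray, divergence: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. substitutions at the divergence rate; every hit changes the base."""
    out = codes.copy()
    if divergence <= 0:
        return out
    mask = rng.random(len(codes)) < divergence
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def plant_te_family(
    genome: GenomeModel,
    spec: TEFamilySpec,
    rng: np.random.Generator,
    consensus: str | None = None,
    occupancy: _Occupancy | None = None,
    max_tries_per_copy: int = 200,
) -> tuple[GenomeModel, list[TEInstance], str]:
    """Plant ``copy_number`` decayed consensus copies, uniformly, overlap-free.

    Returns the mutated genome, the instances, and the consensus used.
    Copies are placed on the forward strand; decay is i.i.d. substitution
    at the family's divergence rate (no indels).
    """
    if genome.sequences is None:
        raise ValueError("genome must carry sequences")
    if spec.consensus_length > min(genome.chrom_lengths.values()):
        raise ValueError("consensus longer than the shortest chromosome")
    if consensus is None:
        consensus = decode_sequence(
            _random_codes(spec.consensus_length, genome.background, rng)
        )
    cons_codes = encode_sequence(consensus)
    occupancy = _Occupancy() if occupancy is None else occupancy

    chroms = list(genome.chrom_lengths)
    placeable = np.array(
        [genome.chrom_lengths[c] - spec.consensus_length + 1 for c in chroms],
        dtype=float,
    )
    chrom_p = placeable / placeable.sum()
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}

    instances: list[TEInstance] = []
    for i in range(spec.copy_number):
        placed = False
        for _ in range(max_tries_per_copy):
            chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
            start = int(
                rng.integers(0, genome.chrom_lengths[chrom] - spec.consensus_length + 1)
            )
            end = start + spec.consensus_length
            if occupancy.is_free(chrom, start, end):
                occupancy.add(chrom, start, end)
                copy = _mutate_copy(cons_codes, spec.divergence, rng)
                seqs[chrom][start:end] = decode_sequence(copy).encode("ascii")
                instances.append(
                    TEInstance(
                        interval=GenomicInterval(chrom, start, end, "+"),
                        name=spec.name,
                        te_class=spec.te_class,
                        instance_id=f"{spec.name}_{i:05d}",
                    )
                )
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place copy {i} of {spec.name} without overlap "
                f"after {max_tries_per_copy} tries"
            )
    new_sequences = {c: s.decode("ascii") for c, s in seqs.items()}
    mutated = GenomeModel(
        chrom_lengths=dict(genome.chrom_lengths),
        sequences=new_sequences,
        background=empirical_background(new_sequences),
    )
    return mutated, instances, consensus


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def background_overlap_rate(
    genome: GenomeModel, instances: Sequence[TEInstance], window_size: int
) -> float:
    """Probability that a uniformly placed window overlaps >=1 instance.

    Instances are overlap-free by construction, so the rate is the summed
    per-instance footprint (len + window - 1) over the placeable positions,
    ignoring chromosome-edge effects (negligible at Mb scale).
    """
    placeable = sum(
        max(l - window_size + 1, 1) for l in genome.chrom_lengths.values()
    )
    footprint = sum(t.interval.length + window_size - 1 for t in instances)
    return min(1.0, footprint / placeable)


def generate_peaks(
    genome: GenomeModel,
    tes: Sequence[TEInstance],
    multipliers: Mapping[str, float],
    n_peaks: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> tuple[list[Peak], dict[str, str | None], dict[str, float]]:
    """Peaks whose expected family-overlap rate is k_f times background.

    For family f with multiplier k_f and background rate b_f, each peak is
    planted on a uniformly chosen f instance with probability
    p_f = (k_f - 1) b_f / (1 - b_f) and placed uniformly otherwise, so the
    total expected overlap fraction is exactly min(1, k_f * b_f); with all
    multipliers at 1 every peak is placed uniformly (the exact null).
    Returns (peaks, per-peak planted family, per-family b_f).
    """
    if n_peaks <= 0:
        raise ValueError("n_peaks must be > 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    by_family: dict[str, list[TEInstance]] = {}
    for t in tes:
        by_family.setdefault(t.name, []).append(t)

    fams = sorted(f for f in multipliers if multipliers[f] != 1.0 and f in by_family)
    b = {
        f: background_overlap_rate(genome, by_family[f], window_size) for f in fams
    }
    p_plant = []
    for f in fams:
        target = multipliers[f] * b[f]
        if target > 1.0:
            logger.warning(
                "family %s: requested overlap fraction %.3f > 1; clipped", f, target
            )
            target = 1.0
        p_plant.append(max(0.0, (target - b[f]) / (1.0 - b[f])))
    total = sum(p_plant)
    if total > 1.0:
        logger.warning("planting probabilities sum to %.3f > 1; rescaled", total)
        p_plant = [p / total for p in p_plant]
    probs = np.array(p_plant + [1.0 - sum(p_plant)])

    chroms = list(genome.chrom_lengths)
    placeable = np.array(
        [genome.chrom_lengths[c] - window_size + 1 for c in chroms], dtype=float
    )
    chrom_p = placeable / placeable.sum()

    choice = rng.choice(len(fams) + 1, size=n_peaks, p=probs)
    peaks: list[Peak] = []
    assignment: dict[str, str | None] = {}
    for i in range(n_peaks):
        pid = f"peak_{i:05d}"
        if choice[i] < len(fams):
            fam = fams[choice[i]]
            inst = by_family[fam][rng.integers(0, len(by_family[fam]))]
            lo = max(0, inst.interval.start - window_size + 1)
            hi = min(
                genome.chrom_lengths[inst.interval.chrom] - window_size,
                inst.interval.end - 1,
            )
            start = int(rng.integers(lo, hi + 1))
            chrom = inst.interval.chrom
            assignment[pid] = fam
        else:
            chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
            start = int(rng.integers(0, genome.chrom_lengths[chrom] - window_size + 1))
            assignment[pid] = None
        iv = GenomicInterval(chrom, start, start + window_size)
        peaks.append(Peak(id=pid, interval=iv, window=iv))
    return peaks, assignment, b


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def generate_genes(
    genome: GenomeModel,
    tes: Sequence[TEInstance],
    n_genes: int,
    tss_near_te_fraction: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    near_distance: int = 2000,
) -> tuple[list[GeneAnnotation], dict[str, str | None]]:
    """Genes whose TSSs are near a planted TE for the stated fraction."""
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    chroms = list(genome.chrom_lengths)
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lens / lens.sum()
    tes = list(tes)
    genes: list[GeneAnnotation] = []
    truth: dict[str, str | None] = {}
    for i in range(n_genes):
        gid = f"gene_{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if tes and rng.random() < tss_near_te_fraction:
            inst = tes[rng.integers(0, len(tes))]
            lo = max(0, inst.interval.start - near_distance)
            hi = min(
                genome.chrom_lengths[inst.interval.chrom] - 1,
                inst.interval.end - 1 + near_distance,
            )
            tss = int(rng.integers(lo, hi + 1))
            chrom = inst.interval.chrom
            truth[gid] = inst.instance_id
        else:
            chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
            tss = int(rng.integers(0, genome.chrom_lengths[chrom]))
            truth[gid] = None
        genes.append(GeneAnnotation(gene_id=gid, chrom=chrom, tss=tss, strand=strand))
    return genes, truth


# ---------------------------------------------------------------------------
# synteny
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def generate_synteny(
    genome: GenomeModel,
    tes: Sequence[TEInstance],
    spec: SyntenySpec,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    min_block: int = 10_000,
) -> tuple[GenomeModel, list[TEInstance], list[SyntenyBlock], list[tuple[str, str]]]:
    """Second genome = the first, cut into blocks, shuffled, partly inverted.

    TE instances fully inside a block are conserved with probability
    ``conserved_te_fraction`` (annotated in genome B at their projected
    coordinates); the rest have their genome-B sequence overwritten with
    background bases and are not annotated.  Decoy instances of families
    absent from genome A are added to B.  Returns (genome B, TEs in B,
    block table, conserved (id_a, id_b) pair truth).
    """
    if genome.sequences is None:
        raise ValueError("genome must carry sequences")
    rng = np.random.default_rng(seed) if rng is None else rng
    chroms = list(genome.chrom_lengths)
    if spec.n_blocks < len(chroms):
        raise ValueError("need at least one block per chromosome")

    # allocate block counts per chromosome, proportional to length
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.maximum(1, np.floor(spec.n_blocks * lens / lens.sum()).astype(int))
    while alloc.sum() < spec.n_blocks:
        alloc[int(np.argmax(lens / alloc))] += 1
    while alloc.sum() > spec.n_blocks:
        i = int(np.argmax(alloc))
        if alloc[i] > 1:
            alloc[i] -= 1

    a_spans: list[tuple[str, int, int]] = []
    for c, n_i in zip(chroms, alloc):
        L = genome.chrom_lengths[c]
        if n_i == 1:
            a_spans.append((c, 0, L))
            continue
        for _ in range(1000):
            cuts = np.sort(rng.integers(min_block, L - min_block + 1, size=n_i - 1))
            bounds = np.concatenate([[0], cuts, [L]])
            if np.all(np.diff(bounds) >= min_block):
                break
        else:
            raise RuntimeError(f"could not cut {c} into {n_i} blocks of >= {min_block}")
        for s, e in zip(bounds[:-1], bounds[1:]):
            a_spans.append((c, int(s), int(e)))

    order = rng.permutation(len(a_spans))
    inverted = rng.random(len(a_spans)) < spec.inversion_fraction

    blocks: list[SyntenyBlock] = []
    b_parts: list[str] = []
    cursor = 0
    for rank, idx in enumerate(order):
        chrom, s, e = a_spans[idx]
        seq = genome.sequences[chrom][s:e]
        inv = bool(inverted[idx])
        if inv:
            seq = _revcomp(seq)
        blocks.append(
            SyntenyBlock(
                block_id=f"block_{rank:03d}",
                interval_a=GenomicInterval(chrom, s, e),
                interval_b=GenomicInterval("chrB1", cursor, cursor + (e - s)),
                orientation="inverted" if inv else "same",
            )
        )
        b_parts.append(seq)
        cursor += e - s
    b_seq = bytearray("".join(b_parts), "ascii")

    # sort blocks per A chromosome for containment lookup
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for blk in blocks:
        by_chrom.setdefault(blk.interval_a.chrom, []).append(blk)

    tes_b: list[TEInstance] = []
    conserved: list[tuple[str, str]] = []
    n_b = 0
    for te in tes:
        home = None
        for blk in by_chrom.get(te.interval.chrom, []):
            if (
                blk.interval_a.start <= te.interval.start
                and te.interval.end <= blk.interval_a.end
            ):
                home = blk
                break
        if home is None:
            continue  # spans a block boundary: treated as not conserved
        proj = project_interval(home, te.interval)
        if rng.random() < spec.conserved_te_fraction:
            n_b += 1
            strand = te.interval.strand
            if home.orientation == "inverted" and strand in ("+", "-"):
                strand = "-" if strand == "+" else "+"
            te_b = TEInstance(
                interval=GenomicInterval(proj.chrom, proj.start, proj.end, strand),
                name=te.name,
                te_class=te.te_class,
                instance_id=f"teB_{n_b:05d}",
            )
            tes_b.append(te_b)
            conserved.append((te.instance_id, te_b.instance_id))
        else:
            filler = decode_sequence(
                _random_codes(proj.length, genome.background, rng)
            )
            b_seq[proj.start : proj.end] = filler.encode("ascii")

    # decoy annotations in B only, under family names absent from A
    occupied = sorted((t.interval.start, t.interval.end) for t in tes_b)
    for i in range(spec.n_decoys):
        for _ in range(200):
            start = int(rng.integers(0, len(b_seq) - 150 + 1))
            j = bisect_left(occupied, (start, start))
            clash = (j < len(occupied) and occupied[j][0] < start + 150) or (
                j > 0 and occupied[j - 1][1] > start
            )
            if not clash:
                insort(occupied, (start, start + 150))
                tes_b.append(
                    TEInstance(
                        interval=GenomicInterval("chrB1", start, start + 150, "+"),
                        name=f"SYN_DECOY_{i:02d}",
                        te_class="DECOY",
                        instance_id=f"decoyB_{i:03d}",
                    )
                )
                break

    genome_b = GenomeModel.from_sequences({"chrB1": b_seq.decode("ascii")})
    return genome_b, tes_b, blocks, conserved


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SimulationResult:
    """Run every generator under one master seed and collect ground truth."""
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    pwms = generate_pwms(config.pwm_specs, rng, background=genome.background)
    pwm_map = {p.id: p for p in pwms}
    consensus = build_family_consensus(config, pwm_map, rng, genome.background)

    truth = GroundTruth()
    occupancy = _Occupancy()
    all_tes: list[TEInstance] = []
    for fam in config.te_families:
        genome, instances, _ = plant_te_family(
            genome, fam, rng, consensus=consensus[fam.name], occupancy=occupancy
        )
        all_tes.extend(instances)
        for pm in config.planted_motifs:
            if pm.family != fam.name:
                continue
            w = pwm_map[pm.pwm_id].width
            for inst in instances:
                s = inst.interval.start + pm.offset
                truth.planted_motif_sites.append(
                    PlantedMotifSite(
                        pm.pwm_id, fam.name, inst.instance_id,
                        GenomicInterval(inst.interval.chrom, s, s + w),
                    )
                )
        for sp in config.planted_spacings:
            if sp.family != fam.name:
                continue
            for inst in instances:
                a = inst.interval.start + sp.offset_a
                truth.planted_spacing_sites.append(
                    PlantedSpacingSite(
                        sp.pwm_a, sp.pwm_b, inst.instance_id,
                        a, a + sp.distance, sp.distance,
                    )
                )
    truth.te_instances = all_tes
    truth.family_multipliers = {
        fam.name: float(config.enrichment_multipliers.get(fam.name, 1.0))
        for fam in config.te_families
    }

    peaks: list[Peak] = []
    if config.n_peaks:
        peaks, assignment, b_rates = generate_peaks(
            genome,
            all_tes,
            config.enrichment_multipliers,
            config.n_peaks,
            rng=rng,
            window_size=config.window_size,
        )
        truth.peak_families = assignment
        truth.background_overlap = b_rates

    genes: list[GeneAnnotation] = []
    if config.n_genes:
        genes, gene_truth = generate_genes(
            genome,
            all_tes,
            config.n_genes,
            config.tss_near_te_fraction,
            rng=rng,
            near_distance=config.tss_near_distance,
        )
        truth.gene_te = gene_truth

    result = SimulationResult(
        config=config,
        genome=genome,
        tes=all_tes,
        peaks=peaks,
        genes=genes,
        pwms=pwms,
        consensus=consensus,
        truth=truth,
    )
    if config.synteny is not None:
        genome_b, tes_b, blocks, conserved = generate_synteny(
            genome, all_tes, config.synteny, rng=rng
        )
        result.genome_b = genome_b
        result.tes_b = tes_b
        result.blocks = blocks
        truth.conserved_pairs = conserved
    return result


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Write the simulated study as FASTA / BED / TSV / JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome_fasta(result.genome, out / "genome_a.fa")
    write_chrom_sizes(result.genome.chrom_lengths, out / "genome_a.sizes")
    write_tes_bed(result.tes, out / "tes_a.bed")
    write_peaks_bed(result.peaks, out / "peaks.bed")
    write_genes(result.genes, out / "genes.tsv")
    if result.genome_b is not None:
        write_genome_fasta(result.genome_b, out / "genome_b.fa")
        write_tes_bed(result.tes_b or [], out / "tes_b.bed")
        write_blocks_tsv(result.blocks or [], out / "synteny_blocks.tsv")
    cfg = asdict(result.config)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    truth = {
        "family_multipliers": result.truth.family_multipliers,
        "background_overlap": result.truth.background_overlap,
        "peak_families": result.truth.peak_families,
        "gene_te": result.truth.gene_te,
        "conserved_pairs": result.truth.conserved_pairs,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
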