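"""Conserved-TE detection through syntenic block coordinate projection.

A syntenic block maps an interval of genome A linearly onto an interval of
genome B, optionally inverted.  A TE instance in A is conserved when its
projected span is matched by a same-family instance in B with sufficient
reciprocal overlap.  This mirrors the cross-species (human-mouse style)
conserved-repeat bookkeeping: blocks are *inputs* (real compara exports or
simulated); no alignment is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .core_model import GenomicInterval, TEInstance


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: str
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    orientation: str  # "same" | "inverted"

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValueError("orientation must be 'same' or 'inverted'")


@dataclass(frozen=True)
class ConservedPair:
    te_a: TEInstance
    te_b: TEInstance
    block_id: str
    reciprocal_overlap: float

    def __post_init__(self) -> None:
        if not (0.0 < self.reciprocal_overlap <= 1.0):
            raise ValueError("reciprocal_overlap must be in (0, 1]")
        # family-level matching is the default; class-level pairs (flagged
        # matching) must still share the repeat class
        if (
            self.te_a.name != self.te_b.name
            and self.te_a.te_class != self.te_b.te_class
        ):
            raise ValueError("conserved pairs must share the family name or class")


def project_interval(
    block: SyntenyBlock, interval: GenomicInterval, direction: str = "a_to_b"
) -> GenomicInterval:
    """Project an interval through one block; inverted blocks flip order.

    Equal-length blocks map exactly; unequal lengths are linearly
    interpolated.  Raises if the interval is not contained in the source
    side of the block.
    """
    if direction == "a_to_b":
        src, dst = block.interval_a, block.interval_b
    elif direction == "b_to_a":
        src, dst = block.interval_b, block.interval_a
    else:
        raise ValueError("direction must be 'a_to_b' or 'b_to_a'")
    if (
        interval.chrom != src.chrom
        or interval.start < src.start
        or interval.end > src.end
    ):
        raise ValueError(f"{interval} not in block {block.block_id} ({src})")
    scale = dst.length / src.length
    off_start = interval.start - src.start
    off_end = interval.end - src.start
    if block.orientation == "same":
        start = dst.start + round(off_start * scale)
        end = dst.start + round(off_end * scale)
    else:
        start = dst.end - round(off_end * scale)
        end = dst.end - round(off_start * scale)
    return GenomicInterval(dst.chrom, start, max(end, start + 1))


def find_conserved_te_pairs(
    tes_a: Sequence[TEInstance],
    tes_b: Sequence[TEInstance],
    blocks: Sequence[SyntenyBlock],
    min_reciprocal_overlap: float = 0.5,
    match_level: str = "family",
) -> list[ConservedPair]:
    """Pair each genome-A TE with its best same-family match in genome B.

    The TE's span (its largest in-block fragment, if it straddles a
    boundary) is projected through the block; any genome-B instance of the
    same family (or class, with ``match_level="class"``) whose reciprocal
    overlap with the projection reaches the threshold is a candidate, and
    the best one (largest overlap, ties toward the smaller B coordinate) is
    kept.  Reciprocal overlap = min(|∩|/|projection|, |∩|/|te_b|).
    """
    if match_level not in ("family", "class"):
        raise ValueError("match_level must be 'family' or 'class'")
    key = (lambda t: t.name) if match_level == "family" else (lambda t: t.te_class)

    blocks_by_chrom: dict[str, list[SyntenyBlock]] = {}
    for blk in blocks:
        blocks_by_chrom.setdefault(blk.interval_a.chrom, []).append(blk)
    b_index: dict[tuple[str, str], list[TEInstance]] = {}
    for tb in tes_b:
        b_index.setdefault((key(tb), tb.interval.chrom), []).append(tb)

    pairs: list[ConservedPair] = []
    for ta in tes_a:
        best_block, best_len = None, 0
        for blk in blocks_by_chrom.get(ta.interval.chrom, []):
            inter = ta.interval.intersection_length(blk.interval_a)
            if inter > best_len:
                best_block, best_len = blk, inter
        if best_block is None:
            continue
        frag = GenomicInterval(
            ta.interval.chrom,
            max(ta.interval.start, best_block.interval_a.start),
            min(ta.interval.end, best_block.interval_a.end),
        )
        proj = project_interval(best_block, frag)
        best: ConservedPair | None = None
        for tb in b_index.get((key(ta), proj.chrom), []):
            inter = proj.intersection_length(tb.interval)
            if inter == 0:
                continue
            ro = min(inter / proj.length, inter / tb.interval.length)
            if ro < min_reciprocal_overlap:
                continue
            if (
                best is None
                or ro > best.reciprocal_overlap
                or (
                    ro == best.reciprocal_overlap
                    and tb.interval.start < best.te_b.interval.start
                )
            ):
                best = ConservedPair(
                    te_a=ta, te_b=tb, block_id=best_block.block_id,
                    reciprocal_overlap=ro,
                )
        if best is not None:
            pairs.append(best)
    return pairs


# ---------------------------------------------------------------------------
# block table I/O
# ---------------------------------------------------------------------------

def write_blocks_tsv(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#block_id\tchromA\tstartA\tendA\tchromB\tstartB\tendB\torientation\n")
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.interval_a.chrom}\t{b.interval_a.start}"
                f"\t{b.interval_a.end}\t{b.interval_b.chrom}\t{b.interval_b.start}"
                f"\t{b.interval_b.end}\t{b.orientation}\n"
            )


def read_blocks_tsv(path: str | Path) -> list[SyntenyBlock]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            blocks.append(
                SyntenyBlock(
                    block_id=f[0],
                    interval_a=GenomicInterval(f[1], int(f[2]), int(f[3])),
                    interval_b=GenomicInterval(f[4], int(f[5]), int(f[6])),
                    orientation=f[7],
                )
            )
    return blocks


def write_pairs_tsv(pairs: Iterable[ConservedPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#te_a\tfamily\tchromA\tstartA\tendA\tte_b\tchromB\tstartB\tendB"
            "\tblock_id\treciprocal_overlap\n"
        )
        for p in pairs:
            a, b = p.te_a.interval, p.te_b.interval
            fh.write(
                f"{p.te_a.instance_id}\t{p.te_a.name}\t{a.chrom}\t{a.start}\t{a.end}"
                f"\t{p.te_b.instance_id}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{p.block_id}\t{p.reciprocal_overlap:.4f}\n"
            )
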