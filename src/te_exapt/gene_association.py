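"""Peak-to-gene assignment, TE-to-TSS distances, and functional enrichment.

A gene is called putatively regulated when a peak midpoint falls inside a
±20 kb window around its TSS; joining the peak's TE-overlap annotation then
associates each TE family with a set of putative target genes.  TE-to-TSS
distance histograms (signed relative to gene strand, upstream negative)
describe how the retained elements sit with respect to genes.  The
downstream ontology step is a generic one-sided hypergeometric test with
Benjamini–Hochberg correction over user-supplied gene→category tables, the
background being the full set of linked genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_model import GeneAnnotation, Peak, TEInstance

logger = logging.getLogger(__name__)

DEFAULT_HALF_WINDOW = 20_000


@dataclass(frozen=True)
class GenePeakLink:
    gene_id: str
    peak_id: str
    te_families: tuple[str, ...]
    distance: int  # TSS -> peak midpoint, negative upstream of the gene


@dataclass(frozen=True)
class CategoryEnrichment:
    category: str
    k: int  # linked genes in category
    K: int  # background genes in category
    n: int  # linked genes tested
    N: int  # background size
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")
        if not (0.0 < self.p <= 1.0 and 0.0 < self.q <= 1.0):
            raise ValueError("p and q must be in (0, 1]")


def peak_te_families(
    peaks: Sequence[Peak], tes: Sequence[TEInstance]
) -> dict[str, tuple[str, ...]]:
    """Families of TE instances overlapping each peak window."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for t in tes:
        trees.setdefault(t.interval.chrom, IntervalTree()).addi(
            t.interval.start, t.interval.end, t.name
        )
    out: dict[str, tuple[str, ...]] = {}
    for p in peaks:
        tree = trees.get(p.window.chrom)
        fams = (
            sorted({iv.data for iv in tree.overlap(p.window.start, p.window.end)})
            if tree
            else []
        )
        out[p.id] = tuple(fams)
    return out


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    half_window: int = DEFAULT_HALF_WINDOW,
    te_families: Mapping[str, tuple[str, ...]] | None = None,
    mode: str = "midpoint",
) -> list[GenePeakLink]:
    """Link genes to peaks within ±half_window of the TSS.

    ``mode="midpoint"`` (default) requires the peak midpoint inside the
    window, making the ±20 kb bound exact; ``mode="overlap"`` accepts any
    window overlap.  A peak may link many genes and vice versa.  Distances
    are signed relative to the gene strand (upstream negative).
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError("mode must be 'midpoint' or 'overlap'")
    links: list[GenePeakLink] = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.window.chrom, []).append(p)
    for g in genes:
        lo, hi = g.tss - half_window, g.tss + half_window
        for p in by_chrom.get(g.chrom, []):
            mid = p.window.midpoint
            if mode == "midpoint":
                hit = lo <= mid <= hi
            else:
                hit = p.window.start <= hi and p.window.end > lo
            if not hit:
                continue
            signed = mid - g.tss if g.strand == "+" else g.tss - mid
            links.append(
                GenePeakLink(
                    gene_id=g.gene_id,
                    peak_id=p.id,
                    te_families=(te_families or {}).get(p.id, ()),
                    distance=signed,
                )
            )
    return links


@dataclass
class TssDistanceHistogram:
    distances: np.ndarray  # one signed distance per usable TE
    bin_edges: np.ndarray
    counts: np.ndarray
    n_excluded: int


def te_tss_distance_hist(
    tes: Sequence[TEInstance],
    genes: Sequence[GeneAnnotation],
    bin_width: int = 1000,
    max_distance: int | None = None,
) -> TssDistanceHistogram:
    """Signed distance from each TE midpoint to its nearest TSS, binned.

    Nearest is by absolute genomic distance; equidistant TSSs break toward
    the smaller coordinate.  Sign is relative to the chosen gene's strand
    (upstream negative).  TEs on chromosomes without genes are excluded and
    logged.  Bins are half-open, ``[edge_i, edge_{i+1})``.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda g: (g.tss, g.gene_id))

    dists: list[int] = []
    n_excluded = 0
    for te in tes:
        glist = by_chrom.get(te.interval.chrom)
        if not glist:
            n_excluded += 1
            continue
        mid = te.interval.midpoint
        tss = np.array([g.tss for g in glist])
        i = int(np.searchsorted(tss, mid))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(glist):
                d = abs(glist[j].tss - mid)
                # tie toward the smaller coordinate: left neighbour first
                if best is None or d < best[0]:
                    best = (d, glist[j])
        assert best is not None
        g = best[1]
        signed = mid - g.tss if g.strand == "+" else g.tss - mid
        dists.append(signed)
    if n_excluded:
        logger.warning("%d TEs on chromosomes without genes excluded", n_excluded)
    arr = np.array(dists, dtype=np.int64)
    if max_distance is None:
        max_distance = int(np.abs(arr).max()) + bin_width if len(arr) else bin_width
    lo = -(max_distance // bin_width + 1) * bin_width
    hi = (max_distance // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    return TssDistanceHistogram(
        distances=arr, bin_edges=edges, counts=counts, n_excluded=n_excluded
    )


def functional_enrichment(
    gene_set: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> list[CategoryEnrichment]:
    """One-sided hypergeometric enrichment with BH correction.

    ``categories`` maps category id → member genes.  The background must
    contain every tested gene; categories with no background members are
    skipped and logged.  p = P[X >= k] for X ~ Hypergeom(N, K, n); q is
    Benjamini–Hochberg across the tested categories.
    """
    from scipy.stats import hypergeom
    from statsmodels.stats.multitest import multipletests

    bg = set(background)
    gs = set(gene_set)
    if not gs <= bg:
        raise ValueError("background must contain every tested gene")
    N, n = len(bg), len(gs)
    rows: list[tuple[str, int, int]] = []
    for cat, members in categories.items():
        K = len(set(members) & bg)
        if K == 0:
            logger.info("category %s absent from background; skipped", cat)
            continue
        k = len(set(members) & gs)
        rows.append((cat, k, K))
    if not rows:
        return []
    ps = np.array(
        [
            1.0 if (k == 0 and n == 0) else float(hypergeom.sf(k - 1, N, K, n))
            for _, k, K in rows
        ]
    )
    ps = np.clip(ps, np.finfo(float).tiny, 1.0)
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    return [
        CategoryEnrichment(category=cat, k=k, K=K, n=n, N=N, p=float(p), q=float(q))
        for (cat, k, K), p, q in zip(rows, ps, qs)
    ]


def write_links_tsv(links: Iterable[GenePeakLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tpeak_id\tte_families\tdistance\n")
        for l in links:
            fams = ",".join(l.te_families) or "."
            fh.write(f"{l.gene_id}\t{l.peak_id}\t{fams}\t{l.distance}\n")


def write_enrichment_table(
    rows: Iterable[CategoryEnrichment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("#category\tk\tK\tn\tN\tp\tq\n")
        for r in rows:
            fh.write(
                f"{r.category}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\t{r.q:.6g}\n"
            )
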