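# Methods

This note records the statistical model behind each stage, the defaults
and why they are what they are, what the synthetic data does and does not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer.

## Coordinates and peak windows

All features use 0-based half-open intervals; RepeatMasker `.out`
(1-based inclusive) is converted on read.  Each peak carries a fixed
200 bp analysis window centred on the geometric midpoint
`floor((start+end)/2)`; the window is `[mid−100, mid+100)`.  Whether
"middle" should mean a summit call is unknowable from a coordinate-only
peak table, so the geometric midpoint is used.  Windows running past a
chromosome end are clipped **and flagged**: flagged peaks stay in all
interval arithmetic but are excluded from sequence scanning (scanning a
truncated window would bias per-window hit probabilities).  Peak strand is
ignored throughout; TE strand is carried but distances and overlaps are
computed on the forward strand.

## Family enrichment z-scores

For family *r*: `x_r` = number of **distinct** TE instances whose span
shares ≥ 1 bp with ≥ 1 peak window.  An instance under two windows counts
once; a window over two instances increments both families.  Instance-level
counting is the primary unit because the enrichment is a property of repeat
copies, not of peaks; per-peak counting (`unit="peak"`) is available.

The null model matches local peak density: each chromosome is divided into
fixed 1 Mb windows anchored at position 0; each random peak keeps its real
counterpart's length and is placed uniformly inside the 1 Mb window
containing the real midpoint (trailing partial windows used as-is; windows
shorter than the peak fall back to whole-chromosome placement, logged).
Random peaks may overlap each other and real peaks — no exclusion, since
the scheme is plain uniform placement within the window.  With `n_random`
replicates (default 1000), `z = (x − μ)/√s` uses the unbiased sample
variance; the estimator choice is immaterial at n = 1000 but must be
pinned.  Zero-variance families are flagged degenerate (z = 0 if `x = μ`,
signed infinity otherwise) rather than silently dropped.  A master seed
spawns one child generator per replicate and the child seeds are recorded,
so any replicate can be re-run exactly.  Enrichment calls use `z > 3`
(strict).

Counting is implemented as a sorted-start/prefix-max-end sweep over numpy
arrays (exact, `O((n+m) log)`), cross-checked in the tests against
nested-loop and per-base oracles.

## PWM scoring, calibration and TAS

PWMs are count matrices normalised with a pseudocount of 0.25 per base
(standard small-sample correction; 0.25 corresponds to one pseudo-
observation spread over the alphabet).  Scoring is the log2 likelihood
ratio against the background composition — the empirical genome
composition, strand-symmetrised (A=T, C=G averaged), since scanning covers
both strands.  `N` bases contribute 0.  Both strands of each 200 bp window
are scanned; a reverse-strand hit at position p scores the reverse
complement of the word starting at p.

Thresholds are calibrated **per window, not per position**: the target is
P(random 200 bp background window contains ≥ 1 hit) = 0.01, i.e. the TAS
of pure background is 0.01.  Monte Carlo with `n_mc = 10,000` windows:
take each window's maximum score over positions and strands and set the
threshold at the empirical 99th percentile of the maxima, so exactly 1% of
calibration windows carry a hit.  Ties in the discrete score distribution
can push the achieved rate slightly above target; the achieved rate is
recorded in the calibration report, and the validation check (independent
windows) is within 3 binomial standard errors of 0.01 for every fixture
PWM.  A matrix whose score distribution is too flat to reach the target
(e.g. a background-equal PWM) raises an error naming it.

TAS(family, TF) = carrying / instances, where the instance set is exactly
the set counted by the enrichment stage and an instance *carries* the TF
iff some hit in an overlapping window has its matched bases intersecting
the instance's span ("span" mode; "window" mode — any hit anywhere in the
window — is a flag).  Span intersection is the default because TAS is
meant as an affinity of the element itself.  The TE × TF matrix fills
missing cells with 0; putative interactors are TFs with TAS ≥ 0.10
(inclusive — ten times the chance rate; the boundary convention is a
choice, flagged here) in ≥ 1 family.  Heat-map leaf orders come from
average-linkage agglomerative clustering on Euclidean distances, with
name-sorted input so ties are deterministic.

## Spacing correlators

For two hit sets A and B, every (a, b) pair within a window contributes
one count at the signed start-to-start distance `d = start(b) − start(a)`
on the forward strand (hit strand ignored; the fixed-spacing biology is a
distance constraint, not a strand constraint).  All pairs are counted, not
nearest pairs.  When A and B are the same matrix, coincident positions are
excluded as self-pairs.  Swapping A and B mirrors the histogram exactly.

The modal distance (ties → smallest |d|, then smallest d) is tested by
permutation: hit positions are redrawn uniformly per window, preserving
per-window hit counts, and the null statistic is the maximum histogram
count; `p = (1 + #{null ≥ observed}) / (n_perm + 1)`.  An explicit
permutation null is supplied because no analytic null accounts for the
per-window hit multiplicities.

The conserved-core report globally aligns each instance to a family core
with match +1 / mismatch −1 / linear gap −2 (configurable; the alignment
backend is Bio.Align's Needleman–Wunsch, cross-checked against a textbook
DP in the tests).  Per-core-position identity counts gaps as mismatches.
Calibrated PWMs annotate core hits; an instance hit mapping to a core
position with no core hit of the same matrix is flagged as a site-creating
mutation.  Instances shorter than half the core are skipped (a global
alignment of a fragment against the full core mostly measures gap
penalties).

## Gene association

A gene is linked to a peak when the peak window's midpoint lies within
±20 kb of the TSS (inclusive).  Midpoint containment, not any-overlap,
keeps the bound exact; any-overlap is a flag.  Transcript tables should be
collapsed to one TSS per gene (smallest coordinate on +, largest on −)
before use.  TE-to-TSS distances use the nearest TSS by absolute distance
(ties toward the smaller coordinate), signed relative to the gene strand
(upstream negative).  Functional enrichment is a one-sided hypergeometric
upper tail per category with Benjamini–Hochberg adjustment across the
categories of one gene set; the background is the full linked-gene set,
which makes the test conditional on being regulated at all.

## Synteny projection

Blocks map linearly (inverted blocks reverse endpoint order); equal-length
blocks — all simulated ones — round-trip exactly, unequal lengths are
interpolated with rounding.  A TE is paired with the best same-family
instance in the other genome whose reciprocal overlap with the projected
span is ≥ 0.5, reciprocal overlap being
`min(|∩|/|projection|, |∩|/|target|)` — the standard conservative
criterion; threshold and class-level matching are flags.  TEs straddling a
block boundary are projected through the block holding their largest
fragment.

## The synthetic study

Defaults (the standing test conditions): two 5 Mb chromosomes at GC 0.41;
50 TE families, each 200 copies of a 150 bp consensus decayed by i.i.d.
substitutions at rate 0.10 (≈ 15% repeat content — mammalian-like order of
magnitude; 200 copies × 350 bp effective footprint gives per-family
background window-overlap rates b ≈ 0.007, so a fivefold family yields
≈ 70 overlapping peaks and ≥ 30 distinct overlapped instances among 2,000
peaks); 2,000 peaks of 200 bp; fixture PWM panel of widths 8–15 with one
dominant base per position (counts 12–24 against 0–2, giving a near-
continuous score distribution so threshold quantiles have no heavy ties);
500 genes with 30% of TSSs within 2 kb of a TE.

Peak enrichment control: a family with multiplier k has each peak planted
on one of its instances with probability `(k−1)·b/(1−b)` and placed
uniformly otherwise, which makes the total expected overlap fraction
exactly `min(1, k·b)` and makes k = 1 degenerate to pure uniform placement
(the exact null).  Requested fractions above 1 are clipped with a warning.

The second genome cuts the first into n blocks (≥ 10 kb each), shuffles
them into one chromosome, reverse-complements a configured fraction, and
carries a configured fraction of fully-in-block TE instances across
(others have their target-side sequence overwritten with background);
decoy annotations under family names absent from genome A are added so
recovery precision is actually tested.

What the generator does **not** emulate: insertion biology (no target-site
duplications, no nesting, no indel decay — identity per copy is exactly
binomial), GC isochores or mappability structure (background is i.i.d., so
the local-window matching of the null is exercised but not stressed),
transcript structure (genes are bare TSSs), and lineage structure in the
synteny map (blocks are a permutation, not a phylogeny).  Passing tests
therefore demonstrate correctness of the statistics under their own
assumptions, not robustness to real-genome confounders such as
composition-driven peak placement.

## Problem sizes used in the checks

The acceptance-grade checks run at: calibration/validation 10,000 + 10,000
windows per PWM; null z calibration at the standing study size with 200
random sets; planted-enrichment recovery over 20 replicate peak sets at
100 random sets each (the planted z sits near 10, far from the 3 cutoff,
so 100 replicates resolve it comfortably); spacing recovery on 40 copies
at divergence 0.05 with 1,000 permutations; oracle equivalence on 100
random small fixtures.  Decoy families occasionally exceed z = 3 —
with ~980 null family×replicate draws a few exceedances are expected from
the null itself — so the recovery check requires the planted family to
outrank every decoy in every replicate and decoy exceedances to stay
within the 2% null allowance, rather than demanding zero, which no correct
implementation could guarantee.
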