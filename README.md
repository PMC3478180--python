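# te_exapt

Transposable-element (TE) exaptation analysis for ChIP-seq peak sets.

A sizeable fraction of transcription-factor binding sites in mammalian
genomes sits inside relics of ancient transposable elements: the repeat
brought a ready-made piece of regulatory sequence with it, and the host
co-opted ("exapted") it.  Given a ChIP-seq peak set (the motivating case is
ERα occupancy in breast-cancer cells), a repeat annotation, a genome and a
panel of position weight matrices, this package asks:

* **Which TE families are enriched under the peaks?**  For every family
  *r*, count the distinct repeat instances overlapped by the 200 bp windows
  centred on the peaks (`x_r`), rebuild the peak set 1000 times by
  redrawing each peak uniformly inside the 1 Mb genomic window that
  contains it (so local density is matched), and report

  `z_r = (x_r − μ_r) / √s_r`

  with `μ_r`, `s_r` the mean and variance of the count over the random
  sets; families with `z > 3` are called enriched.  The same is done per
  repeat class (`z_c`).
* **Which TFs do those families host?**  Each PWM's log-odds threshold is
  calibrated by Monte Carlo so a *random* 200 bp window contains ≥ 1 hit
  with probability 0.01.  The **Transposon Affinity Score** (TAS) of family
  ×TF is then the fraction of the family's peak-overlapping instances
  carrying a hit inside their span — 0.01 by chance, so a TAS ≥ 0.10 (ten
  times chance) flags a putative interactor.  The full TE × TF matrix is
  reported with hierarchical-clustering leaf orders for heat-map display.
* **Do TF pairs sit at a fixed spacing?**  All (A, B) hit pairs per window
  are histogrammed by signed start-to-start distance; the modal distance
  gets a permutation p-value (positions redrawn uniformly per window,
  per-window hit counts preserved).  A conserved-core report aligns decayed
  copies to a family core (e.g. the ~70 bp MIR core) and annotates
  conserved, lost and newly created binding sites.
* **Are the elements near genes, and are those genes coherent?**  Peaks are
  linked to genes whose TSS lies within ±20 kb; per-TE gene sets feed a
  hypergeometric + Benjamini–Hochberg enrichment over user-supplied
  categories.
* **Are the elements conserved across species?**  TE spans are projected
  through syntenic blocks; same-family instances in the second genome with
  reciprocal overlap ≥ 0.5 are reported as conserved pairs.

Everything is exercisable without any download: `te_exapt.synthetic_data`
generates multi-chromosome genomes with planted TE families (decayed
consensus copies), peak sets with controlled per-family enrichment
multipliers, motif pairs planted at exact spacings, TSSs near TEs, and a
block-shuffled second genome with known conserved instances — all with full
ground truth for testing.

## Worked example

```python
from te_exapt import SimulationConfig, simulate, enrichment_zscores, filter_enriched
from te_exapt.synthetic_data import default_te_families

cfg = SimulationConfig(
    seed=1,
    chrom_lengths={"chr1": 1_000_000},
    te_families=default_te_families(10, 150, 60, 0.10),
    n_peaks=1000,
    enrichment_multipliers={"FAM03": 5.0},   # 5x the background overlap rate
)
study = simulate(cfg)
run = enrichment_zscores(study.peaks, study.tes, study.genome, n_random=200, seed=7)
for r in filter_enriched(run.results, z_min=3):
    print(f"{r.level:6s} {r.unit:12s} x={r.x:3d} mu={r.mu:6.2f} var={r.var:6.2f} z={r.z:5.2f}")
```

prints

```
family FAM03        x= 48 mu= 17.84 var= 10.93 z= 9.12
class  DNA/hAT-Charlie x= 66 mu= 35.23 var= 20.29 z= 6.83
```

FAM03 — the one family planted at five times its background overlap rate —
is overlapped by 48 distinct instances against 17.8 ± 3.3 expected under
local resampling (z = 9.1), and it drags its repeat class above the z = 3
cutoff with it; the nine decoy families all stay below the cutoff.

The same objects drive the rest of the pipeline, e.g.:

```python
from te_exapt import calibrate_threshold, compute_tas, tas_matrix

pwm = calibrate_threshold(study.pwms[0], study.genome.background, seed=5)
records = compute_tas(study.peaks, study.tes, study.genome.sequences, pwm)
matrix = tas_matrix(records, tas_min=0.10)
```

A `te-exapt` command-line tool wraps the major stages (`simulate`,
`partition`, `enrich`, `tas`, `correlate`, `annotate`, `conserve`); each
subcommand reads and writes plain BED/FASTA/TSV.

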