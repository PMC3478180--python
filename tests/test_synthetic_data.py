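"""Ground-truth generators: determinism, planted structure, binomial checks."""

import numpy as np
import pytest

from te_exapt.core_model import GenomeModel
from te_exapt.synthetic_data import (
    PWMSpec,
    SimulationConfig,
    TEFamilySpec,
    default_te_families,
    generate_genes,
    generate_genome,
    generate_peaks,
    generate_pwms,
    plant_motif_combination,
    plant_te_family,
)
from te_exapt.te_enrichment import count_te_overlaps
from te_exapt.tfbs_affinity import calibrate_threshold, scan_sequence


def small_config(**kw):
    defaults = dict(
        seed=7,
        chrom_lengths={"chr1": 100_000},
        te_families=[],
        n_peaks=10,
        n_genes=10,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_gc_content_concentrates(self):
        cfg = small_config(gc_content=0.5)
        g = generate_genome(cfg)
        seq = g.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_same_seed_is_bit_identical(self):
        cfg = small_config()
        assert generate_genome(cfg).sequences == generate_genome(cfg).sequences

    def test_gc_one_gives_only_gc(self):
        g = generate_genome(small_config(gc_content=1.0, chrom_lengths={"c": 2000}))
        assert set(g.sequences["c"]) <= {"G", "C"}


class TestTEPlanting:
    def test_zero_divergence_copies_identical(self, rng):
        g = generate_genome(small_config())
        spec = TEFamilySpec("F", "SINE/MIR", 120, 10, 0.0)
        mutated, instances, consensus = plant_te_family(g, spec, rng)
        for inst in instances:
            assert mutated.fetch(inst.interval) == consensus

    def test_divergence_matches_binomial_oracle(self, rng):
        g = generate_genome(small_config(chrom_lengths={"chr1": 500_000}))
        spec = TEFamilySpec("F", "SINE/MIR", 200, 100, 0.10)
        mutated, instances, consensus = plant_te_family(g, spec, rng)
        idents = [
            np.mean([a == b for a, b in zip(mutated.fetch(i.interval), consensus)])
            for i in instances
        ]
        assert 0.88 <= np.mean(idents) <= 0.92

    def test_zero_copies_leaves_genome_unchanged(self, rng):
        g = generate_genome(small_config())
        spec = TEFamilySpec("F", "SINE/MIR", 120, 0, 0.1)
        mutated, instances, _ = plant_te_family(g, spec, rng)
        assert instances == [] and mutated.sequences == g.sequences

    def test_planted_instances_do_not_overlap(self, rng):
        g = generate_genome(small_config())
        spec = TEFamilySpec("F", "SINE/MIR", 150, 50, 0.1)
        _, instances, _ = plant_te_family(g, spec, rng)
        spans = sorted((i.interval.start, i.interval.end) for i in instances)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestMotifPlanting:
    def test_planted_distance_exact(self, rng):
        pwms = generate_pwms([PWMSpec("A", 10), PWMSpec("B", 8)], rng)
        cons = "A" * 100
        planted = plant_motif_combination(cons, pwms[0], pwms[1], 20, 24)
        assert planted[20:30] == pwms[0].consensus_word()
        assert planted[44:52] == pwms[1].consensus_word()

    def test_overlapping_sites_rejected_unless_allowed(self, rng):
        pwms = generate_pwms([PWMSpec("A", 10), PWMSpec("B", 8)], rng)
        with pytest.raises(ValueError):
            plant_motif_combination("A" * 100, pwms[0], pwms[1], 20, 0)
        planted = plant_motif_combination(
            "A" * 100, pwms[0], pwms[1], 20, 0, allow_overlap=True
        )
        assert planted[20:28] == pwms[1].consensus_word()

    def test_planted_sites_beat_calibrated_threshold(self, rng):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwms = generate_pwms([PWMSpec("A", 10), PWMSpec("B", 8)], rng, background=bg)
        cal = [calibrate_threshold(p, bg, n_mc=2000, rng=rng) for p in pwms]
        cons = "".join(rng.choice(list("ACGT"), 100))
        planted = plant_motif_combination(cons, cal[0], cal[1], 20, 24)
        hits_a = {pos for pos, s, _ in scan_sequence(planted, cal[0]) if s == "+"}
        hits_b = {pos for pos, s, _ in scan_sequence(planted, cal[1]) if s == "+"}
        assert 20 in hits_a and 44 in hits_b


class TestPeaks:
    def test_multiplier_matches_binomial_oracle(self, rng):
        g = generate_genome(small_config(chrom_lengths={"chr1": 1_000_000}))
        spec = TEFamilySpec("F", "SINE/MIR", 150, 30, 0.1)
        g, tes, _ = plant_te_family(g, spec, rng)
        k, n = 5.0, 10_000
        peaks, _, b = generate_peaks(g, tes, {"F": k}, n, rng=rng)
        fam_counts, _ = count_te_overlaps(peaks, tes, unit="peak")
        expected = k * b["F"] * n
        sd = np.sqrt(n * k * b["F"] * (1 - k * b["F"]))
        assert abs(fam_counts["F"] - expected) <= 4 * sd

    def test_null_multiplier_plants_nothing(self, rng):
        g = generate_genome(small_config())
        spec = TEFamilySpec("F", "SINE/MIR", 150, 10, 0.1)
        g, tes, _ = plant_te_family(g, spec, rng)
        _, assignment, _ = generate_peaks(g, tes, {"F": 1.0}, 500, rng=rng)
        assert all(v is None for v in assignment.values())

    def test_same_seed_identical_peaks(self):
        g = generate_genome(small_config())
        p1, _, _ = generate_peaks(g, [], {}, 100, seed=3)
        p2, _, _ = generate_peaks(g, [], {}, 100, seed=3)
        assert p1 == p2

    def test_planted_truth_is_self_consistent(self, rng):
        """Re-deriving overlap labels from coordinates reproduces the truth."""
        g = generate_genome(small_config(chrom_lengths={"chr1": 300_000}))
        spec = TEFamilySpec("F", "SINE/MIR", 150, 30, 0.1)
        g, tes, _ = plant_te_family(g, spec, rng)
        peaks, assignment, _ = generate_peaks(g, tes, {"F": 8.0}, 300, rng=rng)
        spans = [(t.interval.start, t.interval.end) for t in tes]
        for p in peaks:
            if assignment[p.id] == "F":
                assert any(
                    p.window.start < e and p.window.end > s for s, e in spans
                )


class TestGenes:
    def test_fraction_one_all_near_te(self, rng):
        g = generate_genome(small_config())
        g, tes, _ = plant_te_family(g, TEFamilySpec("F", "X/Y", 150, 20, 0.1), rng)
        genes, truth = generate_genes(g, tes, 50, 1.0, rng=rng)
        by_id = {t.instance_id: t for t in tes}
        for gene in genes:
            inst = by_id[truth[gene.gene_id]]
            assert inst.interval.start - 2000 <= gene.tss <= inst.interval.end + 2000

    def test_fraction_zero_no_truth(self, rng):
        g = generate_genome(small_config())
        g, tes, _ = plant_te_family(g, TEFamilySpec("F", "X/Y", 150, 20, 0.1), rng)
        _, truth = generate_genes(g, tes, 50, 0.0, rng=rng)
        assert all(v is None for v in truth.values())

    def test_fraction_matches_binomial_oracle(self, rng):
        g = generate_genome(small_config())
        g, tes, _ = plant_te_family(g, TEFamilySpec("F", "X/Y", 150, 20, 0.1), rng)
        _, truth = generate_genes(g, tes, 500, 0.3, rng=rng)
        n_near = sum(v is not None for v in truth.values())
        assert abs(n_near - 150) <= 4 * np.sqrt(500 * 0.3 * 0.7)


class TestSynteny:
    def test_identity_synteny_preserves_everything(self, rng):
        from te_exapt.synthetic_data import SyntenySpec, generate_synteny

        g = generate_genome(small_config(chrom_lengths={"chr1": 100_000}))
        g, tes, _ = plant_te_family(g, TEFamilySpec("F", "X/Y", 150, 20, 0.1), rng)
        spec = SyntenySpec(
            n_blocks=1, inversion_fraction=0.0, conserved_te_fraction=1.0, n_decoys=0
        )
        gb, tes_b, blocks, conserved = generate_synteny(g, tes, spec, rng=rng)
        assert gb.sequences["chrB1"] == g.sequences["chr1"]
        assert len(conserved) == len(tes)
        assert [t.interval.start for t in tes_b] == [t.interval.start for t in tes]

    def test_zero_conservation_empty_truth(self, rng):
        from te_exapt.synthetic_data import SyntenySpec, generate_synteny

        g = generate_genome(small_config(chrom_lengths={"chr1": 100_000}))
        g, tes, _ = plant_te_family(g, TEFamilySpec("F", "X/Y", 150, 20, 0.1), rng)
        spec = SyntenySpec(
            n_blocks=2, inversion_fraction=0.5, conserved_te_fraction=0.0, n_decoys=0
        )
        _, tes_b, _, conserved = generate_synteny(g, tes, spec, rng=rng)
        assert conserved == [] and tes_b == []


class TestSimulationDeterminism:
    def test_full_simulation_is_reproducible(self, small_study):
        from te_exapt.synthetic_data import simulate

        again = simulate(small_study.config)
        assert again.genome.sequences == small_study.genome.sequences
        assert again.peaks == small_study.peaks
        assert again.tes == small_study.tes
        assert again.truth.conserved_pairs == small_study.truth.conserved_pairs
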