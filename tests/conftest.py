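import numpy as np
import pytest

from te_exapt.core_model import GenomicInterval, Peak
from te_exapt.synthetic_data import (
    PlantedSpacing,
    SimulationConfig,
    SyntenySpec,
    default_te_families,
    simulate,
)


def random_interval(rng, chrom="chr1", max_pos=1000, max_len=100):
    start = int(rng.integers(0, max_pos))
    length = int(rng.integers(1, max_len + 1))
    return GenomicInterval(chrom, start, start + length)


def peak_from_window(pid, chrom, start, end):
    """A peak whose analysis window is exactly [start, end)."""
    iv = GenomicInterval(chrom, start, end)
    return Peak(id=pid, interval=iv, window=iv)


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study shared by unit tests: 400 kb genome,
    5 families x 40 copies, a planted 24 nt motif spacing in FAM00,
    genes near TEs, and a shuffled/inverted syntenic second genome."""
    cfg = SimulationConfig(
        seed=42,
        chrom_lengths={"chr1": 250_000, "chr2": 150_000},
        te_families=default_te_families(5, 150, 40, 0.05),
        planted_spacings=[PlantedSpacing("TF_W10", "TF_W08", "FAM00", 30, 24)],
        n_peaks=400,
        n_genes=120,
        tss_near_te_fraction=0.8,
        synteny=SyntenySpec(
            n_blocks=8, inversion_fraction=0.5, conserved_te_fraction=0.4
        ),
    )
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
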