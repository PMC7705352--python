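import numpy as np
import pytest

from breedhet import GenotypeDataset, SnpRecord, scenario, simulate_dataset


def make_dataset(dosages, breeds=None, chrom=None, positions=None):
    """Hand-build a GenotypeDataset from a plain dosage matrix."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    if breeds is None:
        breeds = ["B"] * (n // 2) + ["F"] * (n - n // 2)
    chrom = chrom or ["1"] * m
    positions = positions or [1000 * (j + 1) for j in range(m)]
    snps = [SnpRecord(f"snp{j}", chrom[j], positions[j], "A", "G")
            for j in range(m)]
    ids = [f"ind{i}" for i in range(n)]
    return GenotypeDataset(ids, list(breeds), snps, dosages)


@pytest.fixture(scope="session")
def small_sim():
    """Two-breed panel with moderate divergence: 60+60 individuals, 200 SNPs."""
    cfg = scenario("allelic_het", n_breed_B=60, n_breed_F=60,
                   n_chromosomes=2, snps_per_chromosome=100, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """Exchangeable-breed panel: no frequency or LD divergence, no QTL."""
    cfg = scenario("null_homogeneous", n_breed_B=80, n_breed_F=80,
                   n_chromosomes=1, snps_per_chromosome=200, seed=7)
    return simulate_dataset(cfg)
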