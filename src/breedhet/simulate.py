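r"""Two-breed genotype and pseudophenotype simulator.

Breed allele frequencies follow the Balding–Nichols model: for ancestral
frequency :math:`p` and drift parameter :math:`c` (the breed-level
:math:`F_{ST}`), the breed frequency is Beta-distributed with parameters
:math:`p(1-c)/c` and :math:`(1-p)(1-c)/c`, so its mean is :math:`p` and its
variance :math:`c\,p(1-p)`.

Linkage disequilibrium is produced by founder-haplotype copying: each breed
carries a pool of founder haplotypes drawn site-wise from the breed
frequencies, and every individual haplotype is a mosaic of founders, the
copied founder switching between adjacent SNPs with a fixed probability.
Small pools and low switch rates give strong, breed-specific LD; a switch
rate of 0.5 with a large pool gives linkage equilibrium.  The phased truth
is retained so downstream r² estimators can be checked against exact
haplotype counts.

The pseudophenotype emulates a breeding value: the sum of configured QTL
effects (optionally breed-specific), a polygenic term built from small
random per-SNP effects, and Gaussian noise scaled so the realised
narrow-sense heritability matches the configured ``h2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_genotypes import GenotypeDataset, SnpRecord

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_pseudophenotypes",
    "simulate_dataset",
    "scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the two-breed generator.

    ``qtl_spec`` entries are ``(snp_index, effect_in_B, effect_in_F)`` with
    indices into the simulated panel (chromosomes concatenated).  Effects are
    per A2-allele-copy on the pseudophenotype scale.  ``snp_spacing_bp``
    controls the physical map (one SNP every ``snp_spacing_bp`` base pairs).
    """

    n_breed_B: int = 200
    n_breed_F: int = 200
    n_chromosomes: int = 2
    snps_per_chromosome: int = 500
    fst_B: float = 0.05
    fst_F: float = 0.05
    founder_pool_size: int = 200  # ~ 2 x diploid Ne ~ 100 for cattle breeds
    founder_pool_size_F: int | None = None  # breed F pool; None = same as B
    recombination_rate_per_snp: float = 0.01
    shared_founders: bool = False
    missing_rate: float = 0.0
    qtl_spec: tuple[tuple[int, float, float], ...] = ()
    h2: float = 0.5
    polygenic_frac: float = 1.0  # fraction of SNPs with small effects (infinitesimal model)
    snp_spacing_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_B", "fst_F"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (0.0 <= self.recombination_rate_per_snp <= 0.5):
            raise ValueError("recombination_rate_per_snp must be in [0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must be in (0, 1]")
        if self.founder_pool_size < 2:
            raise ValueError("founder_pool_size must be >= 2")
        if self.founder_pool_size_F is not None and self.founder_pool_size_F < 2:
            raise ValueError("founder_pool_size_F must be >= 2")
        m = self.n_chromosomes * self.snps_per_chromosome
        for q, _, _ in self.qtl_spec:
            # -1 = "place at a common SNP" (resolved against ancestral freqs)
            if q != -1 and not (0 <= q < m):
                raise ValueError(f"qtl index {q} outside panel of {m} SNPs")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


@dataclass
class SimulationTruth:
    """Ground truth kept alongside a simulated dataset."""

    ancestral_freqs: np.ndarray
    breed_freqs_B: np.ndarray
    breed_freqs_F: np.ndarray
    haplotypes: np.ndarray  # n x 2 x m int8, phased A2 indicators
    true_effects: dict[str, np.ndarray]  # breed -> per-QTL effects
    qtl_indices: np.ndarray | None = None  # resolved panel indices
    true_breeding_values: np.ndarray | None = None


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


def simulate_frequencies(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ancestral and per-breed allele frequencies (Balding–Nichols)."""
    rng = _rng(config.seed, 1)
    m = config.n_snps
    p = rng.uniform(0.05, 0.95, size=m)
    freqs = []
    for c in (config.fst_B, config.fst_F):
        a = p * (1.0 - c) / c
        b = (1.0 - p) * (1.0 - c) / c
        freqs.append(np.clip(rng.beta(a, b), 1e-12, 1 - 1e-12))
    return p, freqs[0], freqs[1]


def _copy_haplotypes(rng: np.random.Generator, founders: np.ndarray,
                     n_hap: int, switch: float, chrom_sizes: list[int]) -> np.ndarray:
    """Mosaic haplotypes copied from a founder pool.

    The founder index performs a jump process along each chromosome: with
    probability ``switch`` between adjacent SNPs a new founder is drawn
    uniformly (possibly the same one).
    """
    k, m = founders.shape
    out = np.empty((n_hap, m), dtype=np.int8)
    start = 0
    for size in chrom_sizes:
        idx = np.empty((n_hap, size), dtype=np.int64)
        idx[:, 0] = rng.integers(0, k, size=n_hap)
        if size > 1:
            switches = rng.random((n_hap, size - 1)) < switch
            draws = rng.integers(0, k, size=(n_hap, size - 1))
            for j in range(1, size):
                idx[:, j] = np.where(switches[:, j - 1], draws[:, j - 1], idx[:, j - 1])
        out[:, start:start + size] = founders[idx, np.arange(start, start + size)[None, :]]
        start += size
    return out


def simulate_genotypes(config: SimulationConfig,
                       freqs: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
                       ) -> tuple[GenotypeDataset, SimulationTruth]:
    """Simulate the two-breed panel; returns the dataset plus phased truth."""
    if freqs is None:
        freqs = simulate_frequencies(config)
    ancestral, fB, fF = freqs
    m = config.n_snps
    if len(fB) != m or len(fF) != m:
        raise ValueError("frequency vectors do not match panel size")
    rng = _rng(config.seed, 2)
    chrom_sizes = [config.snps_per_chromosome] * config.n_chromosomes

    breed_freqs = {"B": fB, "F": fF}
    ns = {"B": config.n_breed_B, "F": config.n_breed_F}
    pool_sizes = {"B": config.founder_pool_size,
                  "F": config.founder_pool_size_F or config.founder_pool_size}
    if config.shared_founders:
        shared = (rng.random((config.founder_pool_size, m)) < ancestral).astype(np.int8)
        pools = {"B": shared, "F": shared}
    else:
        pools = {
            b: (rng.random((pool_sizes[b], m)) < breed_freqs[b]).astype(np.int8)
            for b in ("B", "F")
        }
    hap_blocks, labels, ids = [], [], []
    for b in ("B", "F"):
        haps = _copy_haplotypes(rng, pools[b], 2 * ns[b],
                                config.recombination_rate_per_snp, chrom_sizes)
        hap_blocks.append(haps.reshape(ns[b], 2, m))
        labels += [b] * ns[b]
        ids += [f"{b}{i + 1:04d}" for i in range(ns[b])]
    haplotypes = np.concatenate(hap_blocks, axis=0)
    dosages = haplotypes.sum(axis=1).astype(float)
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    snps = []
    for c in range(config.n_chromosomes):
        for j in range(config.snps_per_chromosome):
            snps.append(SnpRecord(
                snp_id=f"snp{c + 1}_{j + 1}",
                chromosome=str(c + 1),
                position_bp=(j + 1) * config.snp_spacing_bp,
                allele_a1="A", allele_a2="G",
            ))
    dataset = GenotypeDataset(ids, labels, snps, dosages)
    truth = SimulationTruth(
        ancestral_freqs=ancestral, breed_freqs_B=fB, breed_freqs_F=fF,
        haplotypes=haplotypes,
        true_effects={"B": np.array([e for _, e, _ in config.qtl_spec]),
                      "F": np.array([e for _, _, e in config.qtl_spec])},
    )
    return dataset, truth


def simulate_pseudophenotypes(dataset: GenotypeDataset, truth: SimulationTruth,
                              config: SimulationConfig) -> np.ndarray:
    """Breeding-value pseudophenotypes for the simulated individuals.

    genetic value = QTL part (breed-specific effects) + polygenic part
    (N(0, 1/(2 m_poly p q)) effects at a random ``polygenic_frac`` subset of
    SNPs); Gaussian noise is added with variance chosen so the realised
    narrow-sense heritability equals ``h2`` exactly in-sample.  ``h2 = 1``
    returns the genetic value itself.
    """
    rng = _rng(config.seed, 3)
    n, m = dataset.dosages.shape
    # complete dosages from phased truth (phenotype generation ignores missingness)
    dos = truth.haplotypes.sum(axis=1).astype(float)
    g = np.zeros(n)
    breed_arr = np.asarray(dataset.breed_labels)
    qtl_idx = _resolve_qtl_indices(config, truth)
    truth.qtl_indices = qtl_idx
    for q, (_, eB, eF) in zip(qtl_idx, config.qtl_spec):
        eff = np.where(breed_arr == "B", eB, eF)
        g += dos[:, q] * eff
    n_poly = max(1, int(round(config.polygenic_frac * m)))
    poly_idx = rng.choice(m, size=n_poly, replace=False)
    poly_eff = rng.normal(0.0, 1.0 / np.sqrt(n_poly), size=n_poly)
    g += dos[:, poly_idx] @ poly_eff
    var_g = float(np.var(g))
    if config.h2 >= 1.0 or var_g == 0.0:
        noise = np.zeros(n)
    else:
        sd_e = np.sqrt(var_g * (1.0 - config.h2) / config.h2)
        noise = rng.normal(0.0, sd_e, size=n)
    y = g + noise
    truth.true_breeding_values = g
    return y


def _resolve_qtl_indices(config: SimulationConfig,
                         truth: SimulationTruth) -> np.ndarray:
    """Resolve sentinel index -1 to the SNPs nearest ancestral frequency 0.5.

    Several sentinel QTL get distinct SNPs, in order of commonness; explicit
    indices are used as given.
    """
    common_order = iter(np.argsort(np.abs(truth.ancestral_freqs - 0.5),
                                   kind="stable"))
    taken = {q for q, _, _ in config.qtl_spec if q != -1}
    out = []
    for q, _, _ in config.qtl_spec:
        if q != -1:
            out.append(q)
            continue
        for cand in common_order:
            if cand not in taken:
                taken.add(int(cand))
                out.append(int(cand))
                break
    return np.asarray(out, dtype=int)


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[GenotypeDataset, np.ndarray, SimulationTruth]:
    """Convenience wrapper: frequencies -> genotypes -> pseudophenotypes."""
    dataset, truth = simulate_genotypes(config)
    y = simulate_pseudophenotypes(dataset, truth, config)
    return dataset, y, truth


SCENARIOS: dict[str, dict] = {
    # exchangeable breeds: negligible drift, one shared founder pool, no QTL
    "null_homogeneous": dict(fst_B=1e-6, fst_F=1e-6, shared_founders=True,
                             qtl_spec=()),
    # asymmetric drift drives allele-frequency (MAF-ratio) heterogeneity
    "allelic_het": dict(fst_B=0.05, fst_F=0.20),
    # equal drift but very different founder pools -> breed-specific LD
    "ld_het": dict(fst_B=0.05, fst_F=0.05, founder_pool_size=200,
                   founder_pool_size_F=8),
    # one QTL active in breed B only: the cross-breed GWAS heterogeneity case.
    # Placed at a common SNP (index -1); effect 0.30 per allele copy ~ 5% of
    # phenotypic variance at h2 = 0.5 (QTL var 2pq e^2 ~ 0.045 against a
    # polygenic var ~ 0.4, with noise doubling the total).
    "breed_specific_qtl": dict(qtl_spec=((-1, 0.30, 0.0),)),
}


def scenario(name: str, **overrides) -> SimulationConfig:
    """Preset simulation configs for the four study conditions.

    ``null_homogeneous``
        no breed structure at all; every downstream test should be null-calibrated.
    ``allelic_het``
        drift asymmetry (F_ST 0.05 vs 0.20) creating inter-breed MAF divergence.
    ``ld_het``
        founder pools of 200 vs 8 haplotypes: same frequencies, divergent LD.
    ``breed_specific_qtl``
        a single QTL with an effect in breed B and none in breed F.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid: {sorted(SCENARIOS)}")
    params = dict(SCENARIOS[name])
    params.update(overrides)
    return SimulationConfig(**params)
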