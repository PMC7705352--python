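# Methods

## The analysis problem

Two breeds are genotyped on a shared SNP panel and carry one quantitative
pseudophenotype each (a breeding value). The pipeline asks, per breed and
per genomic region: (i) which SNPs are associated (mixed-model GWAS);
(ii) whether the breeds can be distinguished from local genotype structure
(windowed GRM-PCA + Hotelling); (iii) whether an associated SNP shows
allelic heterogeneity (log MAF-ratio); and (iv) whether the local LD
structure differs between breeds (the S statistic), plus the genome-wide LD
decay profile. Together these separate "the architecture really differs"
from "the frequencies/LD differ, so the same causal variant is tagged
differently".

## Models and statistics

### Mixed-model GWAS (`breedhet.mlm`)

Per breed, `u = μ + x b + g + e`, `g ~ N(0, G σ²g)`, `e ~ N(0, I σ²e)`,
with `G` the Yang/GCTA genomic relationship matrix computed from the same
panel (the candidate SNP stays in `G`; no leave-one-chromosome-out). Fitting
uses the spectral trick: one eigendecomposition `G = U S U'` turns the
covariance into `σ²e (δ S + I)` with `δ = σ²g/σ²e`, so REML reduces to a
bounded 1-D search over `log δ` (search interval ±12, Brent; residual scale
profiled out).

The `b = 0` test is a likelihood ratio against the asymptotic χ²₁. REML
likelihoods cannot be compared across different fixed-effect designs, so
the LRT uses Gaussian ML log-likelihoods:

- `lrt-null-vc` (default): variance components frozen at the null REML fit;
  with the covariance known, the LRT is the difference of GLS weighted
  residual sums (one O(n) pass per SNP after rotating the dosage matrix).
- `lrt-exact`: `δ` re-optimised per SNP by ML.

The two modes agree to < 0.5 in log₁₀ p for ≥ 95% of SNPs on simulated
panels (asserted in the suite). Monomorphic SNPs keep NA rows; missing
dosages are mean-imputed with `2p`. FDR is Benjamini–Hochberg (via
statsmodels) per breed across tested SNPs; the operating threshold is
FDR ≤ 0.10.

### Windowed breed differentiation (`breedhet.grm`, `breedhet.heterogeneity`)

SNPs are tiled into non-overlapping 50-SNP windows per chromosome (trailing
short windows kept, flagged). Per window, the combined-sample GRM
`G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))` (monomorphic
SNPs excluded, allele frequencies recomputed per window, missing values
mean-imputed) is eigendecomposed; breeds are compared in the space of the
first k = 10 eigenvectors. With `d` the vector of breed-mean differences of
the coordinates and `V` the pooled within-breed covariance
`((n_B−1)S_B + (n_F−1)S_F)/(n_B+n_F−2)`, the squared Mahalanobis distance
is `D_M = d'V⁻¹d` and

```
T = [n_B n_F/(n_B+n_F)] · [(n_B+n_F−k−1)/(k(n_B+n_F−2))] · D_M
    ~ F(k, n_B+n_F−k−1).
```

Two deliberate readings of ambiguous source material: `V` is the pooled
covariance of **all** k coordinates (a 2-D variant would be inconsistent
with the F(10, n−11) reference), and the default coefficient uses the
textbook `(n_B+n_F−2)` denominator — the printed variant with
`(n_B+2n_F−2)` is available as `formula="as-printed"` for exact
replication, but it does not match the stated F distribution. Singular `V`
(possible in short trailing windows) receives a ridge of `10⁻⁸·tr(V)/k` and
is flagged rather than skipped, since refusal would censor chromosome ends
non-randomly. Eigenvector signs are fixed (largest-magnitude coordinate
positive) purely for reproducible output; `D_M`, `T` and `S` are
sign-invariant, and the suite asserts it.

### Allelic heterogeneity (`maf_ratio_test`)

`z = ln(MAF_F/MAF_B)` treated as N(0, 1), two-sided. Both frequencies are
anchored on the pooled-sample minor allele so they refer to the same
allele; per-breed anchoring could silently compare different alleles. The
N(0,1) null carries no sample-size scaling, so its calibration depends on
frequencies and n — it is implemented exactly as specified (the procedure,
not a corrected version), and the mean |z| is validated only as a *dose
response*: it increases monotonically with the drift gap |F_ST,B − F_ST,F|.
The continuity constant defaults to 0 (breed-monomorphic SNPs yield NA and
are flagged, not tested); a configurable `continuity_eps` (e.g. `1/(2n+2)`)
is provided because such SNPs occur in simulation.

### LD divergence and decay (`breedhet.ld`)

Pairwise `r²` is computed from two-SNP haplotype frequencies. On unphased
genotypes the classical two-locus EM resolves the double-heterozygote
ambiguity; the implementation is vectorised over all pairs of a window
(3×3 genotype-pair count tables via indicator matrix products). Stopping is
decided per pair — a pair freezes when one EM sweep moves every haplotype
frequency by < 10⁻¹², capped at 1,000 sweeps — so results are independent
of how pairs are batched, and the window matrix equals the pair-by-pair
composition exactly. On simulated data, `phase="known"` counts the true
phased haplotypes instead. NA cells (breed-monomorphic loci) are set to 0
in window matrices with the NA fraction reported; windows with > 50% NA
pairs are flagged unusable. With unit leading eigenvectors `e_B, e_F` of
the two breed matrices,

```
S = 2 ( ‖(L_B − L_F) e_B‖² + ‖(L_B − L_F) e_F‖² ),
```

which is ≥ 0, zero iff the matrices act identically on both leading
directions, symmetric under a joint breed swap, and insensitive to
eigenvector sign. The upper summation limit is the window size m (short
windows sum to m). LD decay uses nine distance bins (0–25, 25–50, 50–75,
75–120, 120–200, 200–500, 500–1500, 1500–3000, 3000–5000 kbp), left-open /
right-closed, within-chromosome pairs only; each bin is uniformly
subsampled to `max_pairs_per_bin` (default 2,000) under the run seed.

## The synthetic-data generator (`breedhet.simulate`)

What it emulates, and how:

- **Allele-frequency divergence** — Balding–Nichols: ancestral
  `p ~ U(0.05, 0.95)`; breed frequency
  `~ Beta(p(1−c)/c, (1−p)(1−c)/c)` with `c` the breed F_ST (mean `p`,
  variance `c·p(1−p)`).
- **LD** — founder-haplotype copying: a pool of `founder_pool_size`
  haplotypes per breed drawn site-wise from the breed frequencies; each
  individual haplotype copies a founder, switching to a random founder with
  probability `recombination_rate_per_snp` between adjacent SNPs
  (chromosomes independent). Pool size sets the LD *level* (smaller pool →
  stronger LD, more relatedness), switch rate sets the decay *length*
  (~1/rate SNPs). Phased truth is retained for exact r² oracles.
- **Pseudophenotype** — breeding value = breed-specific QTL effects +
  infinitesimal polygenic term (every SNP carries a N(0, 1/m_poly) effect)
  + Gaussian noise scaled so the realised narrow-sense h² equals `h2`
  exactly in-sample. A QTL index of −1 places the causal variant at the SNP
  with ancestral frequency nearest 0.5, so the intended variance share does
  not depend on a frequency lottery.

Defaults and why: `n = 200 + 200` individuals, 2 chromosomes × 500 SNPs at
1 kbp spacing (desk-scale but large enough for 10–20 windows);
`founder_pool_size = 200` haplotypes ≈ twice a diploid effective population
size of ~100, the standard figure for commercial cattle breeds, and the
reference pool of the `ld_het` preset; switch rate 0.01/SNP → LD decay
length ~100 SNPs ≈ 100 kbp, the scale at which cattle panel LD decays;
`F_ST = 0.05` per breed (typical European cattle breed pairs);
`h2 = 0.5` (breeding values are substantially heritable by construction);
`missing_rate = 0`.

Scenario presets: `null_homogeneous` (F_ST → 10⁻⁶, one shared founder
pool, no QTL — breeds exchangeable, every test should be null-calibrated);
`allelic_het` (F_ST 0.05 vs 0.20); `ld_het` (pools 200 vs 8 at equal
F_ST); `breed_specific_qtl` (one common-SNP QTL, per-allele effect 0.30 ≈
5% of phenotypic variance in breed B, zero in F).

What the generator does **not** model — and hence what passing tests do not
show about real data: realistic demography/pedigree (founder copying is a
stationary caricature), genotyping error beyond uniform missingness,
ascertainment bias of commercial SNP chips, selection, sex chromosomes, or
the count-distribution layer above the breeding values. Calibration and
power statements transfer to real cattle panels only qualitatively.

## Numerical choices

- REML/ML optimisation: `log δ ∈ [−12, 12]`, Brent to 10⁻⁸; GRM
  eigenvalues clipped at 0 (tolerance 10⁻⁶ relative for PSD checks).
- LRT statistics clipped at 0; p-values floored at the smallest positive
  double; FDR computed only over tested (non-NA) rows.
- EM: per-pair freeze at max-frequency-change < 10⁻¹², ≤ 1,000 sweeps;
  initialisation at linkage equilibrium of the marginal frequencies. The
  all-double-heterozygote table has a symmetric likelihood with two modes;
  from the symmetric start EM remains at the symmetric stationary point
  (documented, asserted).
- Window tiling is half-open on (chromosome, position)-sorted indices; QC
  order is individuals (call rate ≥ 0.99) before SNPs (pooled MAF ≥ 0.01),
  so MAF reflects the analysed sample.
- Pipeline outputs are TSV with `%.10g` floats; identical config + seed
  reruns are byte-identical (asserted).

## Known limitations

- The N(0,1) MAF-ratio null is not calibrated in n; treat its FDRs as a
  screening heuristic (by design, to reproduce the published procedure).
- No LOCO: a strong QTL inflates its own window's polygenic background,
  deflating the LRT slightly on small panels; negligible at chip scale.
- The Hotelling scan tests eigenvector coordinates of a data-derived basis;
  the F reference is exact only for Gaussian coordinates, and empirical
  type-I error at α = 0.05 sits within ~±0.015 of nominal at n = 400.
- Under a global null, two breed scans at BH-FDR 0.10 each still report at
  least one hit in ~19% of replicate pairs — an irreducible property of the
  FDR operating point, relevant when interpreting "empty report" frequencies.
- Two-locus EM assumes random mating (HWE) within breed when resolving
  double heterozygotes; strong substructure within a breed would bias r².
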