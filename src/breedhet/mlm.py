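"""Single-SNP mixed-linear-model association on pseudophenotypes.

The model for one breed's breeding values :math:`u` is

.. math:: u = \\mu + x b + g + e, \\qquad
          g \\sim N(0, G\\sigma_g^2), \\quad e \\sim N(0, I\\sigma_e^2),

with :math:`G` the genomic relationship matrix and :math:`x` a single SNP's
0/1/2 dosage.  Variance components are estimated by REML using one spectral
decomposition of :math:`G` followed by 1-D optimisation of the variance
ratio :math:`\\delta = \\sigma_g^2/\\sigma_e^2` (the EMMA device).  The null
hypothesis :math:`b = 0` is tested per SNP with a likelihood-ratio statistic
referred to the asymptotic :math:`\\chi^2_1` distribution, and nominal
p-values are transformed to Benjamini–Hochberg false discovery rates.

Two scan modes are provided:

``lrt-null-vc`` (default)
    variance components are fixed at the null-model REML fit and the LRT
    compares Gaussian log-likelihoods with that covariance known (the
    standard EMMAX-style profile approximation; one O(n) pass per SNP).
``lrt-exact``
    the variance ratio is re-optimised per SNP by maximum likelihood.

The public surface is the statsmodels-style pair
:class:`MixedModelGWAS` / :class:`GWASResults`; the module-level functions
(:func:`fit_null_mlm`, :func:`single_snp_scan`, :func:`bh_fdr`, ...) are the
underlying operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .grm import GRM
from .io_genotypes import GenotypeDataset, pooled_freq

__all__ = [
    "VarianceComponents", "MixedModelGWAS", "GWASResults",
    "fit_null_mlm", "single_snp_scan", "bh_fdr", "significant_hits",
    "correlate_breed_results",
]

_LOG_DELTA_BOUNDS = (-12.0, 12.0)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    log_likelihood: float  # restricted log-likelihood at the optimum
    converged: bool

    @property
    def heritability(self) -> float:
        """sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else np.nan


def _spectral(grm: GRM) -> tuple[np.ndarray, np.ndarray]:
    G = (grm.matrix + grm.matrix.T) / 2.0
    s, U = np.linalg.eigh(G)
    if s.min() < -1e-6 * max(1.0, abs(s.max())):
        raise ValueError(f"GRM is not positive semi-definite (min eig {s.min():.3g})")
    return np.clip(s, 0.0, None), U


def _reml_neg_loglik(log_delta: float, yt: np.ndarray, Xt: np.ndarray,
                     s: np.ndarray) -> float:
    delta = np.exp(log_delta)
    d = delta * s + 1.0
    w = 1.0 / d
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    beta = np.linalg.solve(A, XtW.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(r * r * w))
    n, p = yt.size, Xt.shape[1]
    sigma2 = rss / (n - p)
    _, logdet_A = np.linalg.slogdet(A)
    ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + np.sum(np.log(d))
                 + logdet_A + (n - p))
    return -ll


def _ml_neg_loglik(log_delta: float, yt: np.ndarray, Xt: np.ndarray,
                   s: np.ndarray) -> float:
    delta = np.exp(log_delta)
    d = delta * s + 1.0
    w = 1.0 / d
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(XtW.T @ Xt, XtW.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(r * r * w))
    n = yt.size
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.sum(np.log(d)) + n)
    return -ll


def _optimize_delta(objective, yt, Xt, s) -> tuple[float, float, bool]:
    """Minimise a profiled negative log-likelihood over log-delta."""
    res = optimize.minimize_scalar(
        objective, bounds=_LOG_DELTA_BOUNDS, args=(yt, Xt, s),
        method="bounded", options={"xatol": 1e-8})
    return float(res.x), float(-res.fun), bool(res.success)


def fit_null_mlm(phenotype: np.ndarray, grm: GRM) -> VarianceComponents:
    """REML variance components for ``u = mu + g + e``.

    One eigendecomposition of G, then bounded 1-D search over
    ``log(sigma_g^2/sigma_e^2)``.
    """
    y = np.asarray(phenotype, float)
    if y.ndim != 1 or y.size != grm.n:
        raise ValueError("phenotype length does not match GRM")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    s, U = _spectral(grm)
    yt = U.T @ y
    Xt = U.T @ np.ones((y.size, 1))
    log_delta, ll, ok = _optimize_delta(_reml_neg_loglik, yt, Xt, s)
    delta = np.exp(log_delta)
    d = delta * s + 1.0
    w = 1.0 / d
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(XtW.T @ Xt, XtW.T @ yt)
    r = yt - Xt @ beta
    sigma2_e = float(np.sum(r * r * w)) / (y.size - 1)
    return VarianceComponents(sigma2_g=delta * sigma2_e, sigma2_e=sigma2_e,
                              log_likelihood=ll, converged=ok)


def single_snp_scan(dataset: GenotypeDataset, phenotype: np.ndarray, grm: GRM,
                    mode: str = "lrt-null-vc") -> pd.DataFrame:
    """Scan every SNP with the mixed model; returns the association table.

    Columns: ``snp_id chromosome position_bp effect lrt p fdr``; monomorphic
    (zero-variance) SNPs keep their row with NaN statistics.  FDR is
    computed across the tested SNPs.
    """
    if mode not in ("lrt-null-vc", "lrt-exact"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(phenotype, float)
    s, U = _spectral(grm)
    n = y.size
    yt = U.T @ y
    ones_t = U.T @ np.ones((n, 1))

    # mean-impute missing dosages; flag zero-variance SNPs
    X = dataset.dosages.copy()
    p = pooled_freq(dataset)
    X = np.where(np.isnan(X), 2.0 * p, X)
    testable = np.nanstd(X, axis=0) > 0

    vc = fit_null_mlm(y, grm)
    delta0 = vc.sigma2_g / vc.sigma2_e if vc.sigma2_e > 0 else np.exp(_LOG_DELTA_BOUNDS[1])

    m = dataset.n_snps
    eff = np.full(m, np.nan)
    lrt = np.full(m, np.nan)

    if mode == "lrt-null-vc":
        # covariance fixed at sigma_e^2 (delta0 * s + 1); profile means only
        d = vc.sigma2_g * s + vc.sigma2_e
        w = 1.0 / d
        Xt_all = U.T @ X  # n x m rotated dosages
        # vectorised 2x2 GLS per SNP; with the covariance known the LRT is
        # the difference of weighted residual sums (null minus SNP model)
        a11 = float(np.sum(w * ones_t[:, 0] ** 2))
        a12 = np.einsum("i,i,ij->j", w, ones_t[:, 0], Xt_all)
        a22 = np.einsum("i,ij,ij->j", w, Xt_all, Xt_all)
        b1 = float(np.sum(w * ones_t[:, 0] * yt))
        b2 = np.einsum("i,i,ij->j", w, yt, Xt_all)
        det = a11 * a22 - a12 ** 2
        ok = testable & (det > 1e-12 * np.maximum(a11 * a22, 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            beta0 = (a22 * b1 - a12 * b2) / det
            beta1 = (a11 * b2 - a12 * b1) / det
            ywy = float(np.sum(w * yt * yt))
            rss1 = ywy - (beta0 * b1 + beta1 * b2)
            rss0 = ywy - (b1 * b1) / a11
        eff[ok] = beta1[ok]
        lrt[ok] = np.maximum(rss0 - rss1[ok], 0.0)
    else:  # lrt-exact: re-optimise delta per SNP by ML
        _, ll0_ml, _ = _optimize_delta(_ml_neg_loglik, yt, ones_t, s)
        for j in range(m):
            if not testable[j]:
                continue
            Xt = np.column_stack([ones_t[:, 0], U.T @ X[:, j]])
            log_delta, ll1, _ = _optimize_delta(_ml_neg_loglik, yt, Xt, s)
            d = np.exp(log_delta) * s + 1.0
            w = 1.0 / d
            XtW = Xt * w[:, None]
            beta = np.linalg.solve(XtW.T @ Xt, XtW.T @ yt)
            eff[j] = beta[1]
            lrt[j] = max(2.0 * (ll1 - ll0_ml), 0.0)

    pvals = np.where(np.isnan(lrt), np.nan, stats.chi2.sf(lrt, df=1))
    pvals = np.where(np.isnan(pvals), np.nan, np.clip(pvals, np.nextafter(0, 1), 1.0))
    fdr = np.full(m, np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        fdr[tested] = bh_fdr(pvals[tested])
    table = dataset.snp_frame()[["snp_id", "chromosome", "position_bp"]].copy()
    table["effect"] = eff
    table["lrt"] = lrt
    table["p"] = pvals
    table["fdr"] = fdr
    return table


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * n / j``, capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.isnan(p).any():
        raise ValueError("NaN p-values: filter untested rows before FDR")
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_hits(assoc: pd.DataFrame, fdr_threshold: float = 0.10) -> pd.DataFrame:
    """Rows with ``fdr <= fdr_threshold`` (boundary inclusive), sorted by p."""
    hits = assoc[assoc["fdr"].notna() & (assoc["fdr"] <= fdr_threshold)]
    return hits.sort_values("p", kind="mergesort").reset_index(drop=True)


def correlate_breed_results(assoc_B: pd.DataFrame, assoc_F: pd.DataFrame,
                            top_n: int | None = None) -> dict[str, float]:
    """Pearson correlations of the two breeds' p-values and effects.

    Returns ``r_p_all`` and ``r_effect_all`` over shared tested SNPs, and —
    when ``top_n`` is given — ``r_p_top_B`` / ``r_p_top_F``: the correlation
    restricted to the ``top_n`` smallest-p SNPs of each breed in turn.
    """
    merged = assoc_B.merge(assoc_F, on="snp_id", suffixes=("_B", "_F"))
    merged = merged.dropna(subset=["p_B", "p_F"])
    if len(merged) < 3:
        raise ValueError("need at least 3 shared tested SNPs")
    out = {
        "r_p_all": float(np.corrcoef(merged["p_B"], merged["p_F"])[0, 1]),
        "r_effect_all": float(np.corrcoef(merged["effect_B"], merged["effect_F"])[0, 1]),
        "n_shared": float(len(merged)),
    }
    if top_n is not None:
        for breed, col in (("B", "p_B"), ("F", "p_F")):
            top = merged.nsmallest(min(top_n, len(merged)), col)
            out[f"r_p_top_{breed}"] = float(np.corrcoef(top["p_B"], top["p_F"])[0, 1])
    return out


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class MixedModelGWAS:
    """Single-SNP mixed-model GWAS for one breed's pseudophenotypes.

    Parameters
    ----------
    phenotype : array-like
        One breeding value per individual of ``dataset`` (same order).
    dataset : GenotypeDataset
        Genotypes of the individuals to scan (typically one breed).
    grm : GRM, optional
        Genomic relationship matrix; computed genome-wide from ``dataset``
        when omitted.  The candidate SNP stays in G for its own test.
    mode : {"lrt-null-vc", "lrt-exact"}

    Examples
    --------
    >>> model = MixedModelGWAS.from_breed(dataset, phenotype, breed="B")
    >>> results = model.fit()
    >>> results.summary()          # doctest: +SKIP
    """

    def __init__(self, phenotype, dataset: GenotypeDataset, grm: GRM | None = None,
                 mode: str = "lrt-null-vc"):
        from .grm import compute_grm
        self.phenotype = np.asarray(phenotype, float)
        self.dataset = dataset
        if self.phenotype.size != dataset.n_individuals:
            raise ValueError("phenotype length does not match dataset")
        self.grm = grm if grm is not None else compute_grm(dataset)
        self.mode = mode

    @classmethod
    def from_breed(cls, dataset: GenotypeDataset, phenotype, breed: str,
                   **kwargs) -> "MixedModelGWAS":
        """Restrict a two-breed dataset + phenotype vector to one breed."""
        mask = dataset.breed_mask(breed)
        sub = dataset.subset(individuals=mask)
        y = np.asarray(phenotype, float)[mask]
        return cls(y, sub, **kwargs)

    def fit(self) -> "GWASResults":
        vc = fit_null_mlm(self.phenotype, self.grm)
        table = single_snp_scan(self.dataset, self.phenotype, self.grm,
                                mode=self.mode)
        return GWASResults(model=self, varcomp=vc, table=table)


class GWASResults:
    """Fitted scan: association table, variance components, summaries."""

    def __init__(self, model: MixedModelGWAS, varcomp: VarianceComponents,
                 table: pd.DataFrame):
        self.model = model
        self.varcomp = varcomp
        self.table = table

    def significant_hits(self, fdr_threshold: float = 0.10) -> pd.DataFrame:
        return significant_hits(self.table, fdr_threshold)

    def manhattan_data(self) -> pd.DataFrame:
        """chr, cumulative bp and -log10 p, ready for a Manhattan plot."""
        df = self.table.copy()
        offset, cum = 0, []
        for chrom, grp in df.groupby("chromosome", sort=False):
            cum.append(grp["position_bp"] + offset)
            offset += int(grp["position_bp"].max())
        df["cumulative_bp"] = pd.concat(cum)
        with np.errstate(divide="ignore"):
            df["neglog10_p"] = -np.log10(df["p"])
        return df[["snp_id", "chromosome", "position_bp", "cumulative_bp",
                   "neglog10_p"]]

    def summary(self) -> str:
        vc = self.varcomp
        tested = self.table["p"].notna().sum()
        nhit = len(self.significant_hits())
        lines = [
            "Mixed-model single-SNP GWAS",
            "=" * 43,
            f"individuals:        {self.model.dataset.n_individuals}",
            f"SNPs tested:        {tested} / {self.model.dataset.n_snps}",
            f"mode:               {self.model.mode}",
            f"sigma2_g (REML):    {vc.sigma2_g:.5f}",
            f"sigma2_e (REML):    {vc.sigma2_e:.5f}",
            f"h2 estimate:        {vc.heritability:.4f}",
            f"converged:          {vc.converged}",
            f"hits at FDR<=0.10:  {nhit}",
        ]
        if nhit:
            lines.append("-" * 43)
            lines.append(self.significant_hits().head(10).to_string(index=False))
        return "\n".join(lines)
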