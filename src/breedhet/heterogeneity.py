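"""Breed-differentiation tests: windowed Hotelling T² and the MAF-ratio z.

Per 50-SNP window, the combined-sample GRM is decomposed and the two breeds
are compared in the space of the first k = 10 eigenvectors.  With
:math:`d` the vector of differences between breed-averaged eigenvector
coordinates and :math:`V` the pooled within-breed covariance of those
coordinates, the (squared) Mahalanobis distance is :math:`D_M = d'V^{-1}d`
and the two-sample Hotelling statistic

.. math::

    T = \\frac{n_B n_F}{n_B + n_F}
        \\cdot \\frac{n_B + n_F - k - 1}{k\\,(n_B + n_F - 2)}
        \\cdot d'V^{-1}d
    \\;\\sim\\; F_{k,\\; n_B + n_F - k - 1}

under the null of no breed difference.  A variant replacing the
:math:`(n_B + n_F - 2)` denominator with :math:`(n_B + 2 n_F - 2)`
(``formula="as-printed"``) is exposed for exact replication of a published
typesetting of the coefficient; the standard form is the default because it
is the one consistent with the F reference distribution.

Allelic heterogeneity per SNP uses the log-ratio of the two breeds'
frequencies of the pooled-sample minor allele,
:math:`z = \\ln(\\mathrm{MAF}_F/\\mathrm{MAF}_B)`, referred to N(0, 1).
This null carries no sample-size scaling; it is implemented exactly as
specified and its calibration caveat is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grm import EigenBasis, windowed_eigens
from .io_genotypes import GenotypeDataset, Window, breed_maf, pooled_freq
from .mlm import bh_fdr

__all__ = [
    "mahalanobis_window", "hotelling_test", "window_het_scan",
    "maf_ratio_test", "maf_het_scan",
]

_RIDGE_REL = 1e-8


def _pooled_cov(scores: np.ndarray, mask_B: np.ndarray) -> np.ndarray:
    """Pooled within-breed covariance ((nB-1)S_B + (nF-1)S_F)/(nB+nF-2)."""
    SB = np.cov(scores[mask_B], rowvar=False, ddof=1)
    SF = np.cov(scores[~mask_B], rowvar=False, ddof=1)
    nB, nF = int(mask_B.sum()), int((~mask_B).sum())
    return (np.atleast_2d(SB) * (nB - 1) + np.atleast_2d(SF) * (nF - 1)) / (nB + nF - 2)


def mahalanobis_window(basis: EigenBasis, breed_labels,
                       breed_B: str = "B") -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Breed-mean difference and squared Mahalanobis distance in eigenspace.

    Returns ``(d, D_M, V, ridged)`` where ``d[j]`` is the breed-B minus
    breed-F mean of eigenvector j's coordinates, ``V`` the pooled
    within-breed covariance and ``D_M = d'V^{-1}d``.  A singular ``V`` gets
    a ridge of ``1e-8 * tr(V)/k`` and is flagged ``ridged=True``.
    """
    labels = np.asarray(breed_labels)
    mask_B = labels == breed_B
    if not mask_B.any() or mask_B.all():
        raise ValueError("both breeds must be represented")
    scores = basis.eigenvectors  # n x k coordinates
    k = scores.shape[1]
    nB, nF = int(mask_B.sum()), int((~mask_B).sum())
    if k > min(nB, nF) - 1:
        raise ValueError(f"k={k} too large for group sizes {nB}, {nF}")
    d = scores[mask_B].mean(axis=0) - scores[~mask_B].mean(axis=0)
    V = _pooled_cov(scores, mask_B)
    ridged = False
    try:
        sol = np.linalg.solve(V, d)
        if not np.all(np.isfinite(sol)) or np.linalg.cond(V) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        V = V + np.eye(k) * (_RIDGE_REL * np.trace(V) / k)
        sol = np.linalg.solve(V, d)
        ridged = True
    dm2 = float(d @ sol)
    return d, max(dm2, 0.0), V, ridged


def hotelling_test(d: np.ndarray, V: np.ndarray, n_B: int, n_F: int,
                   formula: str = "standard") -> tuple[float, float]:
    """Two-sample Hotelling test of equal breed means in eigenspace.

    Returns ``(T, p)`` with ``T ~ F(k, n_B + n_F - k - 1)`` under the null.
    ``formula="as-printed"`` swaps the (n_B + n_F - 2) denominator term for
    (n_B + 2 n_F - 2).
    """
    d = np.atleast_1d(np.asarray(d, float))
    V = np.atleast_2d(np.asarray(V, float))
    k = d.size
    df2 = n_B + n_F - k - 1
    if df2 < 1:
        raise ValueError(f"invalid denominator df {df2}")
    dm2 = float(d @ np.linalg.solve(V, d))
    if formula == "standard":
        denom = k * (n_B + n_F - 2)
    elif formula == "as-printed":
        denom = k * (n_B + 2 * n_F - 2)
    else:
        raise ValueError(f"unknown formula {formula!r}")
    T = (n_B * n_F) / (n_B + n_F) * df2 / denom * dm2
    p = float(stats.f.sf(T, k, df2))
    return float(T), max(p, np.nextafter(0, 1))


def window_het_scan(dataset: GenotypeDataset, windows: list[Window],
                    k: int = 10, formula: str = "standard",
                    breed_B: str = "B") -> pd.DataFrame:
    """Mahalanobis + Hotelling over all windows, with genome-wide BH FDR.

    One row per window; skipped (degenerate) windows carry NaN statistics
    and ``status="SKIPPED"``.  FDR is computed across the tested windows.
    """
    bases, status = windowed_eigens(dataset, windows, k=k)
    labels = np.asarray(dataset.breed_labels)
    nB = int((labels == breed_B).sum())
    nF = int((labels != breed_B).sum())
    rows = []
    for w in windows:
        rec = {
            "chromosome": w.chromosome,
            "window_start_bp": dataset.snps[w.start].position_bp,
            "window_end_bp": dataset.snps[w.end - 1].position_bp,
            "start": w.start, "end": w.end, "n_snps": w.size,
            "DM": np.nan, "T": np.nan, "df1": np.nan, "df2": np.nan,
            "p": np.nan, "ridged": False, "status": "SKIPPED",
        }
        if w in bases:
            basis = bases[w]
            d, dm2, V, ridged = mahalanobis_window(basis, labels, breed_B=breed_B)
            T, p = hotelling_test(d, V, nB, nF, formula=formula)
            rec.update(DM=dm2, T=T, df1=basis.k, df2=nB + nF - basis.k - 1,
                       p=p, ridged=ridged, status="OK")
        rows.append(rec)
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    table["fdr"] = np.nan
    if tested.any():
        table.loc[tested, "fdr"] = bh_fdr(table.loc[tested, "p"].to_numpy())
    return table


@dataclass
class MafHetResult:
    snp_id: str
    maf_B: float
    maf_F: float
    z: float
    p: float


def maf_ratio_test(maf_F: float, maf_B: float,
                   continuity_eps: float = 0.0) -> tuple[float, float]:
    """ln(MAF_F/MAF_B) referred to N(0, 1), two-sided.

    ``continuity_eps`` is added to both frequencies before taking the ratio
    (0 by default; breed-monomorphic SNPs then yield NaN, which callers flag
    rather than test).
    """
    fF = maf_F + continuity_eps
    fB = maf_B + continuity_eps
    if fF <= 0.0 or fB <= 0.0:
        return np.nan, np.nan
    z = float(np.log(fF / fB))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, max(p, np.nextafter(0, 1))


def maf_het_scan(dataset: GenotypeDataset, continuity_eps: float = 0.0,
                 snp_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP MAF-ratio test with BH FDR across tested SNPs.

    Both breeds' frequencies are anchored on the pooled-sample minor allele.
    ``snp_ids`` restricts the scan (the original analysis tested only
    GWAS-significant positions); default is all SNPs.
    """
    p_pool = pooled_freq(dataset)
    anchor = p_pool <= 0.5
    mB = breed_maf(dataset, "B", pooled_minor=anchor)
    mF = breed_maf(dataset, "F", pooled_minor=anchor)
    ids = [s.snp_id for s in dataset.snps]
    keep = np.ones(len(ids), bool) if snp_ids is None else np.isin(ids, list(snp_ids))
    rows = []
    for j in np.flatnonzero(keep):
        z, p = maf_ratio_test(mF[j], mB[j], continuity_eps)
        rows.append((ids[j], mB[j], mF[j], z, p))
    table = pd.DataFrame(rows, columns=["snp_id", "maf_B", "maf_F", "z", "p"])
    table["fdr"] = np.nan
    tested = table["p"].notna()
    if tested.any():
        table.loc[tested, "fdr"] = bh_fdr(table.loc[tested, "p"].to_numpy())
    return table
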