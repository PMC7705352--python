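"""Linkage disequilibrium: r², two-locus haplotype EM, the S statistic, decay.

For two SNPs with haplotype frequencies :math:`p_{ij}` (first index: allele
at SNP 1, "1" = alternative allele) the squared correlation is

.. math::

    r^2 = \\frac{(p_{11}p_{22} - p_{12}p_{21})^2}
               {p_{1\\cdot}(1-p_{1\\cdot})\\,p_{\\cdot 1}(1-p_{\\cdot 1})}.

Haplotype frequencies come either from phased truth (simulated data) or from
the classical two-locus EM on unphased genotypes, which resolves the
double-heterozygote phase ambiguity iteratively.  The EM here is vectorised
over all SNP pairs of a window simultaneously.

Inter-breed LD divergence per window is the eigenvector-product statistic

.. math::

    S = 2\\sum_{i=1}^{m}\\left[(v_{iBB}-v_{iFB})^2 + (v_{iBF}-v_{iFF})^2\\right]
      = 2\\left(\\lVert(L_B-L_F)e_B\\rVert^2 + \\lVert(L_B-L_F)e_F\\rVert^2\\right),

where :math:`L_B, L_F` are the two breeds' window r² matrices, :math:`e_B,
e_F` their unit leading eigenvectors, and :math:`v_{ijk}` the i-th element
of :math:`L_j e_k`.  S is invariant to eigenvector sign and symmetric under
a joint breed swap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_genotypes import GenotypeDataset, Window

__all__ = [
    "HaplotypeFreqs", "WindowLD", "DecayProfile", "DECAY_BIN_EDGES_KBP",
    "r2_from_freqs", "estimate_pair_freqs", "window_ld_matrix",
    "s_statistic", "s_scan", "ld_decay",
]

_EM_TOL = 1e-12  # per-pair max haplotype-frequency change per sweep
_EM_MAX_ITER = 1000

# genome-wide decay bins in kbp, assignment left-open / right-closed
DECAY_BIN_EDGES_KBP = (0.0, 25.0, 50.0, 75.0, 120.0, 200.0, 500.0,
                       1500.0, 3000.0, 5000.0)


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-SNP haplotype frequencies; index 1 = alternative allele."""

    p11: float
    p12: float
    p21: float
    p22: float

    def __post_init__(self) -> None:
        total = self.p11 + self.p12 + self.p21 + self.p22
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    @property
    def p1_dot(self) -> float:
        return self.p11 + self.p12

    @property
    def p_dot1(self) -> float:
        return self.p11 + self.p21


def r2_from_freqs(freqs: HaplotypeFreqs) -> float:
    """r² from two-SNP haplotype frequencies; NaN when a locus is monomorphic."""
    pA, pB = freqs.p1_dot, freqs.p_dot1
    denom = pA * (1.0 - pA) * pB * (1.0 - pB)
    if denom <= 0.0:
        return np.nan
    D = freqs.p11 * freqs.p22 - freqs.p12 * freqs.p21
    return float(D * D / denom)


# ---------------------------------------------------------------------------
# vectorised two-locus EM
# ---------------------------------------------------------------------------

def _indicator_stack(g: np.ndarray) -> np.ndarray:
    """3 x n x m stack of dosage-class indicators; missing rows are all-zero."""
    return np.stack([(g == a).astype(float) for a in (0.0, 1.0, 2.0)])


def _em_haplotypes(N: np.ndarray, tol: float = _EM_TOL,
                   max_iter: int = _EM_MAX_ITER) -> tuple[np.ndarray, ...]:
    """EM haplotype frequencies from 3x3 genotype-pair counts.

    ``N[a, b]`` (each an arbitrary-shape array) counts individuals with
    dosage ``a`` at the first SNP and ``b`` at the second.  Returns
    ``(p11, p12, p21, p22)`` arrays of the same shape (NaN where no
    informative individuals).
    """
    H = 2.0 * N.sum(axis=(0, 1))
    valid = H > 0
    Hs = np.where(valid, H, 1.0)
    # phase-unambiguous haplotype counts
    c11 = 2 * N[2, 2] + N[2, 1] + N[1, 2]
    c12 = 2 * N[2, 0] + N[2, 1] + N[1, 0]
    c21 = 2 * N[0, 2] + N[1, 2] + N[0, 1]
    c22 = 2 * N[0, 0] + N[0, 1] + N[1, 0]
    dh = N[1, 1].astype(float)  # double heterozygotes: 11/22 or 12/21
    # initialise at linkage equilibrium of the marginal frequencies
    pA = (2 * N[2].sum(axis=0) + N[1].sum(axis=0)) / Hs
    pB = (2 * N[:, 2].sum(axis=0) + N[:, 1].sum(axis=0)) / Hs
    p11 = pA * pB
    p12 = pA * (1 - pB)
    p21 = (1 - pA) * pB
    p22 = (1 - pA) * (1 - pB)
    # Stopping is decided per pair (a pair freezes once its own update moves
    # every haplotype frequency by < tol), so each pair's trajectory — and
    # hence the result — is independent of how pairs are batched together.
    active = valid.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        num = p11 * p22
        den = num + p12 * p21
        pi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        n11 = (c11 + dh * pi) / Hs
        n12 = (c12 + dh * (1 - pi)) / Hs
        n21 = (c21 + dh * (1 - pi)) / Hs
        n22 = (c22 + dh * pi) / Hs
        delta = np.abs(n11 - p11)
        np.maximum(delta, np.abs(n12 - p12), out=delta)
        np.maximum(delta, np.abs(n21 - p21), out=delta)
        np.maximum(delta, np.abs(n22 - p22), out=delta)
        p11 = np.where(active, n11, p11)
        p12 = np.where(active, n12, p12)
        p21 = np.where(active, n21, p21)
        p22 = np.where(active, n22, p22)
        active = active & (delta >= tol)
    nanfill = np.where(valid, 1.0, np.nan)
    return p11 * nanfill, p12 * nanfill, p21 * nanfill, p22 * nanfill


def _r2_array(p11, p12, p21, p22):
    pA = p11 + p12
    pB = p11 + p21
    denom = pA * (1 - pA) * pB * (1 - pB)
    D = p11 * p22 - p12 * p21
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, D * D / np.where(denom > 0, denom, 1.0), np.nan)
    return r2


def estimate_pair_freqs(g1: np.ndarray, g2: np.ndarray, phase: str = "em",
                        hap1: np.ndarray | None = None,
                        hap2: np.ndarray | None = None) -> HaplotypeFreqs:
    """Haplotype frequencies for one SNP pair.

    ``phase="em"`` runs the two-locus EM on the unphased dosage vectors
    (individuals missing at either SNP are dropped); ``phase="known"``
    counts haplotypes directly from ``hap1``/``hap2`` — flat arrays of
    phased alternative-allele indicators, one entry per haplotype.
    """
    if phase == "known":
        if hap1 is None or hap2 is None:
            raise ValueError("phase='known' requires hap1 and hap2")
        h1 = np.asarray(hap1).ravel().astype(float)
        h2 = np.asarray(hap2).ravel().astype(float)
        n = h1.size
        if n == 0:
            raise ValueError("no haplotypes")
        p11 = float(np.mean(h1 * h2))
        p12 = float(np.mean(h1 * (1 - h2)))
        p21 = float(np.mean((1 - h1) * h2))
        return HaplotypeFreqs(p11, p12, p21, 1.0 - p11 - p12 - p21)
    if phase != "em":
        raise ValueError(f"unknown phase mode {phase!r}")
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    keep = ~np.isnan(g1) & ~np.isnan(g2)
    if keep.sum() < 2:
        raise ValueError("need >= 2 individuals with calls at both SNPs")
    g1, g2 = g1[keep], g2[keep]
    N = np.empty((3, 3))
    for a in range(3):
        for b in range(3):
            N[a, b] = np.sum((g1 == a) & (g2 == b))
    p11, p12, p21, p22 = _em_haplotypes(N[:, :, None, None])
    vals = [float(np.clip(x[0, 0], 0.0, 1.0)) for x in (p11, p12, p21, p22)]
    total = sum(vals)
    return HaplotypeFreqs(*(v / total for v in vals))


# ---------------------------------------------------------------------------
# window LD matrices
# ---------------------------------------------------------------------------

@dataclass
class WindowLD:
    """Per-breed window r² matrix with NA accounting.

    NA pairs (a locus monomorphic within the breed, or no informative
    individuals) are set to 0 in ``matrix``; their fraction is reported and
    windows with more than half the pairs NA are flagged not ``usable``.
    """

    matrix: np.ndarray
    na_fraction: float

    @property
    def usable(self) -> bool:
        return self.na_fraction <= 0.5


def _r2_matrix_em(g: np.ndarray) -> np.ndarray:
    """All-pairs r² for an n x m dosage block via vectorised EM."""
    ind = _indicator_stack(g)  # 3 x n x m
    N = np.einsum("anj,bnk->abjk", ind, ind)
    p11, p12, p21, p22 = _em_haplotypes(N)
    return _r2_array(p11, p12, p21, p22)


def _r2_matrix_known(h: np.ndarray) -> np.ndarray:
    """All-pairs r² from a (2n) x m phased alt-allele indicator block."""
    h = h.astype(float)
    n2 = h.shape[0]
    p11 = (h.T @ h) / n2
    p = h.mean(axis=0)
    D = p11 - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, D * D / np.where(denom > 0, denom, 1.0), np.nan)
    return r2


def window_ld_matrix(dataset: GenotypeDataset, window: Window, breed: str,
                     phase: str = "em",
                     haplotypes: np.ndarray | None = None) -> WindowLD:
    """Within-breed r² matrix for one window (symmetric, unit diagonal).

    ``haplotypes`` (n x 2 x m phased alt indicators aligned with the
    dataset's individuals and SNPs) is required for ``phase="known"``.
    """
    mask = dataset.breed_mask(breed)
    idx = window.indices()
    if phase == "known":
        if haplotypes is None:
            raise ValueError("phase='known' requires the haplotypes array")
        h = haplotypes[mask][:, :, idx].reshape(-1, idx.size)
        r2 = _r2_matrix_known(h)
    elif phase == "em":
        r2 = _r2_matrix_em(dataset.dosages[mask][:, idx])
    else:
        raise ValueError(f"unknown phase mode {phase!r}")
    m = idx.size
    off = ~np.eye(m, dtype=bool)
    na_fraction = float(np.isnan(r2[off]).mean()) if m > 1 else 0.0
    r2 = np.nan_to_num(r2, nan=0.0)
    r2 = (r2 + r2.T) / 2.0
    np.fill_diagonal(r2, 1.0)
    return WindowLD(matrix=np.clip(r2, 0.0, 1.0), na_fraction=na_fraction)


# ---------------------------------------------------------------------------
# S statistic
# ---------------------------------------------------------------------------

def _leading_unit_eigvec(L: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((L + L.T) / 2.0)
    v = vecs[:, -1]
    return v / np.linalg.norm(v)


def s_statistic(L_B: np.ndarray, L_F: np.ndarray) -> float:
    """Eigenvector-product LD-divergence statistic S (>= 0, 0 iff equal action).

    S = 2( ||(L_B - L_F) e_B||^2 + ||(L_B - L_F) e_F||^2 ) with e_B, e_F the
    unit leading eigenvectors of the two matrices.
    """
    L_B = np.asarray(L_B, float)
    L_F = np.asarray(L_F, float)
    if L_B.shape != L_F.shape or L_B.ndim != 2 or L_B.shape[0] != L_B.shape[1]:
        raise ValueError("LD matrices must be square and of equal dimension")
    eB = _leading_unit_eigvec(L_B)
    eF = _leading_unit_eigvec(L_F)
    diff = L_B - L_F
    return float(2.0 * (np.sum((diff @ eB) ** 2) + np.sum((diff @ eF) ** 2)))


def s_scan(dataset: GenotypeDataset, windows: list[Window], phase: str = "em",
           haplotypes: np.ndarray | None = None) -> pd.DataFrame:
    """S per window, with per-breed NA fractions and a usability flag."""
    rows = []
    for w in windows:
        ld_B = window_ld_matrix(dataset, w, "B", phase=phase, haplotypes=haplotypes)
        ld_F = window_ld_matrix(dataset, w, "F", phase=phase, haplotypes=haplotypes)
        usable = ld_B.usable and ld_F.usable
        rows.append({
            "chromosome": w.chromosome,
            "window_start_bp": dataset.snps[w.start].position_bp,
            "window_end_bp": dataset.snps[w.end - 1].position_bp,
            "start": w.start, "end": w.end, "n_snps": w.size,
            "S": s_statistic(ld_B.matrix, ld_F.matrix) if usable else np.nan,
            "na_fraction_B": ld_B.na_fraction,
            "na_fraction_F": ld_F.na_fraction,
            "flag": "OK" if usable else "UNUSABLE",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class DecayProfile:
    """Mean r² by physical-distance bin for one breed."""

    breed: str
    table: pd.DataFrame  # bin_lo_kbp bin_hi_kbp n_pairs mean_r2


def ld_decay(dataset: GenotypeDataset, breed: str,
             max_pairs_per_bin: int = 2000, phase: str = "em",
             seed: int = 0, haplotypes: np.ndarray | None = None) -> DecayProfile:
    """Genome-wide LD decay: mean r² in nine physical-distance bins.

    Within-chromosome SNP pairs are assigned to the bins (left-open,
    right-closed, in kbp); pairs farther apart than 5,000 kbp are excluded.
    Each bin is uniformly subsampled to at most ``max_pairs_per_bin`` pairs
    under ``seed``; empty bins report count 0 and NaN mean.
    """
    rng = np.random.default_rng(seed)
    chroms = np.asarray([s.chromosome for s in dataset.snps])
    pos = np.asarray([s.position_bp for s in dataset.snps], float)
    edges = np.asarray(DECAY_BIN_EDGES_KBP) * 1000.0
    per_bin: list[list[tuple[int, int]]] = [[] for _ in range(len(edges) - 1)]
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        jj, kk = np.triu_indices(idx.size, k=1)
        d = pos[idx[kk]] - pos[idx[jj]]
        bins = np.searchsorted(edges, d, side="left") - 1  # right-closed
        ok = (bins >= 0) & (bins < len(per_bin)) & (d > 0)
        for b, j, k in zip(bins[ok], idx[jj[ok]], idx[kk[ok]]):
            per_bin[b].append((j, k))
    mask = dataset.breed_mask(breed)
    g = dataset.dosages[mask]
    hap = None
    if phase == "known":
        if haplotypes is None:
            raise ValueError("phase='known' requires the haplotypes array")
        hap = haplotypes[mask].reshape(-1, dataset.n_snps).astype(float)
    rows = []
    for b, pairs in enumerate(per_bin):
        n_pairs = len(pairs)
        if n_pairs == 0:
            rows.append((edges[b] / 1000, edges[b + 1] / 1000, 0, np.nan))
            continue
        if n_pairs > max_pairs_per_bin:
            take = rng.choice(n_pairs, size=max_pairs_per_bin, replace=False)
            pairs = [pairs[t] for t in sorted(take)]
        j1 = np.asarray([p[0] for p in pairs])
        j2 = np.asarray([p[1] for p in pairs])
        if phase == "known":
            h1, h2 = hap[:, j1], hap[:, j2]
            n2 = h1.shape[0]
            p11 = (h1 * h2).mean(axis=0)
            pA, pB = h1.mean(axis=0), h2.mean(axis=0)
            D = p11 - pA * pB
            denom = pA * (1 - pA) * pB * (1 - pB)
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(denom > 0, D * D / np.where(denom > 0, denom, 1.0),
                              np.nan)
        else:
            ind = _indicator_stack(g)
            N = np.einsum("anp,bnp->abp", ind[:, :, j1], ind[:, :, j2])
            p11, p12, p21, p22 = _em_haplotypes(N)
            r2 = _r2_array(p11, p12, p21, p22)
        mean = float(np.nanmean(r2)) if np.isfinite(r2).any() else np.nan
        rows.append((edges[b] / 1000, edges[b + 1] / 1000, len(pairs), mean))
    table = pd.DataFrame(rows, columns=["bin_lo_kbp", "bin_hi_kbp",
                                        "n_pairs", "mean_r2"])
    return DecayProfile(breed=breed, table=table)
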