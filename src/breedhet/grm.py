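"""Genomic relationship matrices and their eigendecomposition.

The GRM follows the standard additive estimator of Yang et al. (GCTA /
VanRaden form): with dosages :math:`x_{ij}` and pooled allele frequencies
:math:`p_i`,

.. math::

    G_{jk} = \\frac{1}{m} \\sum_{i=1}^{m}
        \\frac{(x_{ij} - 2p_i)(x_{ik} - 2p_i)}{2 p_i (1 - p_i)},

summing over the m SNPs that are polymorphic in the sample.  Missing
dosages are mean-imputed with :math:`2p_i` (so they contribute nothing
after centering), and allele frequencies are recomputed per SNP subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_genotypes import GenotypeDataset, Window, pooled_freq

__all__ = ["GRM", "EigenBasis", "DegenerateWindowError",
           "compute_grm", "eigen_basis", "windowed_eigens"]


class DegenerateWindowError(ValueError):
    """Raised when no SNP in the requested subset is polymorphic."""


@dataclass
class GRM:
    matrix: np.ndarray
    individual_ids: list[str]
    n_snps_used: int

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("GRM must be square")
        if a.shape[0] != len(self.individual_ids):
            raise ValueError("GRM size does not match individual list")
        self.matrix = a

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_gcta_text(self) -> pd.DataFrame:
        """Lower triangle in GCTA ``.grm.gz`` layout (1-based indices)."""
        rows = []
        for j in range(self.n):
            for k in range(j + 1):
                rows.append((j + 1, k + 1, self.n_snps_used, self.matrix[j, k]))
        return pd.DataFrame(rows, columns=["id1", "id2", "n_snps", "value"])


@dataclass
class EigenBasis:
    """Top-k spectral decomposition of a GRM, eigenvalues descending.

    Eigenvector signs are fixed by making each column's largest-magnitude
    coordinate positive, for reproducible output; every downstream statistic
    is invariant to the choice.
    """

    eigenvectors: np.ndarray  # n x k, orthonormal columns
    eigenvalues: np.ndarray   # k, non-increasing

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]


def _centered_scaled(dataset: GenotypeDataset, idx: np.ndarray) -> tuple[np.ndarray, int]:
    """Mean-imputed, centered, per-SNP scaled dosage block Z with Z Z'/m = G."""
    X = dataset.dosages[:, idx]
    p = pooled_freq(dataset.subset(snps=idx))
    poly = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise DegenerateWindowError(
            f"no polymorphic SNP among the {len(idx)} requested")
    X = X[:, poly]
    p = p[poly]
    X = np.where(np.isnan(X), 2.0 * p, X)
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return Z, int(poly.sum())


def compute_grm(dataset: GenotypeDataset,
                snp_subset: Window | np.ndarray | None = None) -> GRM:
    """GCTA-form GRM on all SNPs or a window/index subset.

    Monomorphic SNPs are excluded from the average; a subset with no
    polymorphic SNP raises :class:`DegenerateWindowError`.
    """
    if dataset.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if snp_subset is None:
        idx = np.arange(dataset.n_snps)
    elif isinstance(snp_subset, Window):
        idx = snp_subset.indices()
    else:
        idx = np.asarray(snp_subset)
    if idx.size == 0:
        raise ValueError("empty SNP subset")
    Z, m_used = _centered_scaled(dataset, idx)
    G = (Z @ Z.T) / m_used
    return GRM(matrix=G, individual_ids=list(dataset.individual_ids),
               n_snps_used=m_used)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    anchor = np.abs(vecs).argmax(axis=0)
    signs = np.sign(vecs[anchor, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def eigen_basis(grm: GRM, k: int = 10) -> EigenBasis:
    """Top-``k`` eigenpairs of a symmetric GRM, descending eigenvalues."""
    G = grm.matrix
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("GRM is not symmetric within tolerance")
    if k > grm.n:
        raise ValueError(f"k={k} exceeds matrix size n={grm.n}")
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    return EigenBasis(eigenvectors=_fix_signs(vecs[:, order]),
                      eigenvalues=vals[order])


def windowed_eigens(dataset: GenotypeDataset, windows: list[Window],
                    k: int = 10) -> tuple[dict[Window, EigenBasis], pd.DataFrame]:
    """One combined-sample EigenBasis per window, plus a per-window status table.

    Windows where the GRM is degenerate (all SNPs monomorphic) are reported
    with status ``SKIPPED`` and omitted from the mapping.
    """
    bases: dict[Window, EigenBasis] = {}
    status = []
    for w in windows:
        try:
            grm = compute_grm(dataset, w)
            bases[w] = eigen_basis(grm, k=min(k, grm.n))
            status.append((w.chromosome, w.start, w.end, "OK", ""))
        except DegenerateWindowError as exc:
            status.append((w.chromosome, w.start, w.end, "SKIPPED", str(exc)))
    table = pd.DataFrame(status, columns=["chromosome", "start", "end",
                                          "status", "detail"])
    return bases, table
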