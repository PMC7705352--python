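"""Genotype panels: containers, PLINK/text-dosage IO, QC and window partitioning.

The central container is :class:`GenotypeDataset`, an individuals x SNPs
dosage matrix (0/1/2 copies of the A2 allele, NaN for missing) together with
a SNP map and a breed label per individual.  Two breeds are expected for the
cross-breed analyses downstream; the labels are free strings (conventionally
``"B"`` and ``"F"``).

Supported on-disk formats:

* PLINK 1 binary triple (``.bed`` SNP-major + ``.bim`` + ``.fam``); the breed
  label rides in the family-ID column of the ``.fam``.
* a plain text-dosage TSV with columns ``individual_id``, ``breed`` and one
  column per SNP id, cells in {0, 1, 2, NA}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SnpRecord",
    "GenotypeDataset",
    "Window",
    "QCReport",
    "GenotypeFormatError",
    "read_genotypes",
    "write_genotypes",
    "qc_filter",
    "make_windows",
    "breed_maf",
    "pooled_freq",
]

MISSING = np.nan


class GenotypeFormatError(ValueError):
    """Malformed genotype file (bad magic bytes, ragged rows, bad cells)."""


@dataclass(frozen=True)
class SnpRecord:
    """One marker of the panel: id, map position (1-based bp) and alleles."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a1: str = "A"
    allele_a2: str = "B"

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"position_bp must be >= 1, got {self.position_bp}")


@dataclass(frozen=True)
class Window:
    """Contiguous run of SNPs on one chromosome, half-open index range.

    Indices refer to the dataset's (chromosome, position)-sorted SNP list.
    ``short`` flags trailing windows smaller than the nominal window size.
    """

    chromosome: str
    start: int
    end: int
    short: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end)


@dataclass(frozen=True)
class QCReport:
    n_snps_in: int
    n_snps_removed_maf: int
    n_individuals_in: int
    n_individuals_removed_callrate: int

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - self.n_snps_removed_maf

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - self.n_individuals_removed_callrate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_snps_in", "n_snps_removed_maf", "n_snps_out",
                    "n_individuals_in", "n_individuals_removed_callrate",
                    "n_individuals_out",
                ],
                "value": [
                    self.n_snps_in, self.n_snps_removed_maf, self.n_snps_out,
                    self.n_individuals_in, self.n_individuals_removed_callrate,
                    self.n_individuals_out,
                ],
            }
        )


@dataclass
class GenotypeDataset:
    """Individuals x SNPs dosage panel with breed labels.

    ``dosages[i, j]`` counts copies of ``snps[j].allele_a2`` carried by
    individual ``i`` (0, 1, 2) or NaN when the call is missing.
    """

    individual_ids: list[str]
    breed_labels: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray  # float array, n x m

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or n != len(self.breed_labels):
            raise ValueError("dosage rows do not match individual list")
        if m != len(self.snps):
            raise ValueError("dosage columns do not match SNP list")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in panel")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.breed_labels:
            seen.setdefault(b, None)
        return list(seen)

    def breed_mask(self, breed: str) -> np.ndarray:
        mask = np.asarray([b == breed for b in self.breed_labels])
        if not mask.any():
            raise KeyError(f"breed {breed!r} not present")
        return mask

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chromosome": [s.chromosome for s in self.snps],
                "position_bp": [s.position_bp for s in self.snps],
                "allele_a1": [s.allele_a1 for s in self.snps],
                "allele_a2": [s.allele_a2 for s in self.snps],
            }
        )

    def sorted_by_position(self) -> "GenotypeDataset":
        """Return a copy with SNPs sorted by (chromosome, position_bp)."""
        order = sorted(
            range(self.n_snps),
            key=lambda j: (_chrom_key(self.snps[j].chromosome), self.snps[j].position_bp),
        )
        return GenotypeDataset(
            individual_ids=list(self.individual_ids),
            breed_labels=list(self.breed_labels),
            snps=[self.snps[j] for j in order],
            dosages=self.dosages[:, order],
        )

    def subset(self, individuals: np.ndarray | None = None,
               snps: np.ndarray | None = None) -> "GenotypeDataset":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        if snp.dtype == bool:
            snp = np.flatnonzero(snp)
        return GenotypeDataset(
            individual_ids=[self.individual_ids[i] for i in ind],
            breed_labels=[self.breed_labels[i] for i in ind],
            snps=[self.snps[j] for j in snp],
            dosages=self.dosages[np.ix_(ind, snp)],
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.breed_labels == other.breed_labels
            and self.snps == other.snps
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


def _chrom_key(label: str):
    """Numeric chromosomes sort numerically, others lexically after them."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


# ---------------------------------------------------------------------------
# text-dosage format
# ---------------------------------------------------------------------------

def _read_text_dosage(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("individual_id", "breed")
    for col in required:
        if col not in df.columns:
            raise GenotypeFormatError(f"{path}: missing column {col!r}")
    snp_cols = [c for c in df.columns if c not in required]
    if not snp_cols:
        raise GenotypeFormatError(f"{path}: no SNP columns")
    raw = df[snp_cols].to_numpy()
    dos = np.empty(raw.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(raw):
        s = str(cell).strip()
        if s in ("NA", "N/A", "nan", ""):
            dos[i, j] = MISSING
        elif s in ("0", "1", "2", "0.0", "1.0", "2.0"):
            dos[i, j] = float(s)
        else:
            raise GenotypeFormatError(
                f"{path}: bad dosage {cell!r} for individual "
                f"{df['individual_id'].iloc[i]!r}, SNP {snp_cols[j]!r}"
            )
    # map information is not carried by the TSV; synthesise consecutive bp
    snps = [SnpRecord(snp_id=c, chromosome="1", position_bp=j + 1)
            for j, c in enumerate(snp_cols)]
    return GenotypeDataset(
        individual_ids=df["individual_id"].tolist(),
        breed_labels=df["breed"].tolist(),
        snps=snps,
        dosages=dos,
    )


def _write_text_dosage(dataset: GenotypeDataset, path: Path) -> None:
    cols: dict[str, list] = {
        "individual_id": dataset.individual_ids,
        "breed": dataset.breed_labels,
    }
    for j, s in enumerate(dataset.snps):
        col = dataset.dosages[:, j]
        cols[s.snp_id] = ["NA" if np.isnan(x) else str(int(x)) for x in col]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK 1 binary triple
# ---------------------------------------------------------------------------
# .bed: magic 0x6c 0x1b, mode 0x01 (SNP-major); then per SNP ceil(n/4) bytes,
# 2 bits per individual, little-endian within a byte:
#   00 = hom A1 (dosage 0 of A2... PLINK counts A1; we count A2 copies:
#        00 -> 0 copies of A2? PLINK's 00 is hom A1 -> dosage of A2 = 0)
#   01 = missing, 10 = het (1), 11 = hom A2 (2)

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit code -> dosage of A2 (NaN = missing)
_CODE_TO_DOSAGE = np.array([0.0, np.nan, 1.0, 2.0])
_DOSAGE_TO_CODE = {0.0: 0b00, 1.0: 0b10, 2.0: 0b11}


def _read_plink(prefix: Path) -> GenotypeDataset:
    bed, bim, fam = (prefix.with_suffix(ext) for ext in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    if fam_df.shape[1] < 2:
        raise GenotypeFormatError(f"{fam}: expected >= 2 columns")
    breed_labels = fam_df[0].tolist()   # family ID column carries the breed
    individual_ids = fam_df[1].tolist()
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    if bim_df.shape[1] != 6:
        raise GenotypeFormatError(f"{bim}: expected 6 columns, got {bim_df.shape[1]}")
    snps = [
        SnpRecord(snp_id=r[1], chromosome=r[0], position_bp=int(r[3]),
                  allele_a1=r[4], allele_a2=r[5])
        for r in bim_df.itertuples(index=False)
    ]
    n, m = len(individual_ids), len(snps)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError(f"{bed}: bad magic/mode bytes {raw[:3]!r}")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise GenotypeFormatError(
            f"{bed}: expected {m * bytes_per_snp} body bytes, got {body.size}")
    mat = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, individual i in byte i//4, bits (2*(i%4))..
    codes = np.empty((m, n), dtype=np.uint8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        codes[:, cols] = (mat[:, cols // 4] >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes].T  # n x m
    return GenotypeDataset(individual_ids, breed_labels, snps, dosages)


def _write_plink(dataset: GenotypeDataset, prefix: Path) -> None:
    n, m = dataset.n_individuals, dataset.n_snps
    fam_rows = [
        f"{b}\t{i}\t0\t0\t0\t-9"
        for i, b in zip(dataset.individual_ids, dataset.breed_labels)
    ]
    prefix.with_suffix(".fam").write_text("\n".join(fam_rows) + "\n")
    bim_rows = [
        f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t{s.allele_a1}\t{s.allele_a2}"
        for s in dataset.snps
    ]
    prefix.with_suffix(".bim").write_text("\n".join(bim_rows) + "\n")
    codes = np.where(
        np.isnan(dataset.dosages), 0b01,
        np.select(
            [dataset.dosages == 0, dataset.dosages == 1, dataset.dosages == 2],
            [0b00, 0b10, 0b11],
        ),
    ).astype(np.uint8).T  # m x n
    bytes_per_snp = (n + 3) // 4
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        packed[:, cols // 4] |= codes[:, cols] << (2 * k)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())


# ---------------------------------------------------------------------------
# public IO
# ---------------------------------------------------------------------------

def read_genotypes(path_prefix: str | Path, format: str = "plink-bed") -> GenotypeDataset:
    """Read a genotype panel; SNPs are returned (chromosome, position)-sorted.

    Parameters
    ----------
    path_prefix
        PLINK prefix (``.bed/.bim/.fam`` appended) or the text-dosage TSV path.
    format
        ``"plink-bed"`` or ``"text-dosage"``.
    """
    p = Path(path_prefix)
    if format == "plink-bed":
        ds = _read_plink(p)
    elif format == "text-dosage":
        ds = _read_text_dosage(p if p.suffix else p.with_suffix(".tsv"))
    else:
        raise ValueError(f"unknown format {format!r}")
    return ds.sorted_by_position()


def write_genotypes(dataset: GenotypeDataset, path_prefix: str | Path,
                    format: str = "plink-bed") -> None:
    """Write a panel so that ``read_genotypes`` round-trips it exactly."""
    if dataset.n_snps == 0:
        raise ValueError("refusing to write an empty-SNP panel")
    p = Path(path_prefix)
    p.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink-bed":
        _write_plink(dataset, p)
    elif format == "text-dosage":
        _write_text_dosage(dataset, p if p.suffix else p.with_suffix(".tsv"))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# frequencies, QC, windows
# ---------------------------------------------------------------------------

def pooled_freq(dataset: GenotypeDataset) -> np.ndarray:
    """Pooled-sample A2 allele frequency per SNP from non-missing calls.

    NaN where a SNP has no non-missing calls.
    """
    with np.errstate(invalid="ignore"):
        return np.nanmean(dataset.dosages, axis=0) / 2.0


def _call_rates(dosages: np.ndarray) -> np.ndarray:
    return 1.0 - np.mean(np.isnan(dosages), axis=1)


def qc_filter(dataset: GenotypeDataset, maf_min: float = 0.01,
              ind_call_rate_min: float = 0.99) -> tuple[GenotypeDataset, QCReport]:
    """Quality control: drop low-call-rate individuals, then low-MAF SNPs.

    Individuals with call rate below ``ind_call_rate_min`` are removed first;
    SNP minor-allele frequencies are then computed on the pooled two-breed
    sample of surviving individuals and SNPs with MAF below ``maf_min``
    (including SNPs with zero non-missing calls) are removed.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= ind_call_rate_min <= 1):
        raise ValueError("ind_call_rate_min must be in [0, 1]")
    n_ind_in, n_snp_in = dataset.n_individuals, dataset.n_snps
    keep_ind = _call_rates(dataset.dosages) >= ind_call_rate_min
    ds = dataset.subset(individuals=keep_ind)
    p = pooled_freq(ds)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep_snp = ~np.isnan(maf) & (maf >= maf_min)
    if not keep_snp.any():
        raise ValueError("QC removed every SNP: empty panel")
    out = ds.subset(snps=keep_snp)
    report = QCReport(
        n_snps_in=n_snp_in,
        n_snps_removed_maf=int((~keep_snp).sum()),
        n_individuals_in=n_ind_in,
        n_individuals_removed_callrate=int((~keep_ind).sum()),
    )
    return out, report


def make_windows(dataset: GenotypeDataset, window_size: int = 50) -> list[Window]:
    """Partition the sorted SNP list into non-overlapping windows.

    Each chromosome is tiled left to right with blocks of ``window_size``
    SNPs; a trailing remainder shorter than ``window_size`` is kept and
    flagged ``short``.  No window spans a chromosome boundary.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    chroms = [s.chromosome for s in dataset.snps]
    # verify sortedness within chromosome
    pos = [s.position_bp for s in dataset.snps]
    windows: list[Window] = []
    start = 0
    for j in range(1, len(chroms) + 1):
        boundary = j == len(chroms) or chroms[j] != chroms[j - 1]
        if j < len(chroms) and not boundary and pos[j] <= pos[j - 1]:
            raise ValueError("dataset SNPs are not position-sorted")
        if boundary:
            for w0 in range(start, j, window_size):
                w1 = min(w0 + window_size, j)
                windows.append(Window(chromosome=chroms[start], start=w0, end=w1,
                                      short=(w1 - w0) < window_size))
            start = j
    return windows


def breed_maf(dataset: GenotypeDataset, breed: str,
              pooled_minor: np.ndarray | None = None) -> np.ndarray:
    """Within-breed frequency of the pooled-sample minor allele, per SNP.

    The minor allele is anchored in the pooled two-breed sample so that both
    breeds' frequencies refer to the same allele (a pooled-minor allele may
    therefore exceed 0.5 within one breed).  SNPs with no non-missing call in
    the breed are NaN.

    Parameters
    ----------
    pooled_minor
        Optional boolean vector, True where the A2 allele is the pooled minor
        allele; computed from the dataset when omitted.
    """
    mask = dataset.breed_mask(breed)
    if pooled_minor is None:
        p = pooled_freq(dataset)
        pooled_minor = p <= 0.5  # A2 is minor (ties: A2)
    sub = dataset.dosages[mask]
    n_called = (~np.isnan(sub)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_a2 = np.where(n_called > 0, np.nansum(sub, axis=0), np.nan) / (2.0 * n_called)
    return np.where(pooled_minor, f_a2, 1.0 - f_a2)
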