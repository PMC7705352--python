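"""End-to-end orchestration: QC -> windows -> GWAS x2 -> heterogeneity -> LD.

A :class:`PipelineConfig` fully determines a run (inputs or simulation
scenario, thresholds, seed); :func:`run_pipeline` executes every stage,
writes each stage's table as TSV under the output directory and returns a
:class:`PipelineResult`.  Reruns with the same config and seed are
byte-identical.  The merged hit report mirrors the layout of a per-SNP
summary table: every GWAS-significant SNP joined with its containing
window's Hotelling FDR, the window's S statistic, and its MAF-ratio FDR.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .heterogeneity import maf_het_scan, window_het_scan
from .io_genotypes import (GenotypeDataset, make_windows, qc_filter,
                           read_genotypes)
from .ld import ld_decay, s_scan
from .mlm import MixedModelGWAS
from .simulate import scenario, simulate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "StageFailure",
           "run_pipeline", "merge_hit_report", "read_phenotypes",
           "write_phenotypes"]

_FLOAT_FMT = "%.10g"


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Serializable configuration of one full analysis run."""

    # input: either a simulation scenario...
    scenario_name: str | None = "breed_specific_qtl"
    scenario_overrides: dict = field(default_factory=dict)
    # ...or genotype + phenotype files
    genotype_prefix: str | None = None
    genotype_format: str = "plink-bed"
    phenotype_file: str | None = None
    # analysis knobs
    maf_min: float = 0.01
    ind_call_rate_min: float = 0.99
    window_size: int = 50
    k: int = 10
    fdr_threshold: float = 0.10
    hotelling_formula: str = "standard"
    phase_mode: str = "em"
    gwas_mode: str = "lrt-null-vc"
    max_pairs_per_bin: int = 2000
    seed: int = 0
    out_dir: str = "breedhet_out"

    def __post_init__(self) -> None:
        # normalise so load(save(c)) == c (YAML has no tuples)
        self.scenario_overrides = _plain(self.scenario_overrides)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(dataclasses.asdict(self)),
                                             sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant fields (output location excluded)."""
        d = _plain(dataclasses.asdict(self))
        d.pop("out_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: pd.DataFrame
    assoc: dict[str, pd.DataFrame]
    window_het: pd.DataFrame
    maf_het: pd.DataFrame
    s_table: pd.DataFrame
    decay: dict[str, pd.DataFrame]
    hit_report: pd.DataFrame
    manifest: dict


def write_phenotypes(path: str | Path, dataset: GenotypeDataset,
                     phenotype: np.ndarray) -> None:
    pd.DataFrame({
        "individual_id": dataset.individual_ids,
        "breed": dataset.breed_labels,
        "phenotype": np.asarray(phenotype, float),
    }).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotypes(path: str | Path, dataset: GenotypeDataset) -> np.ndarray:
    """Phenotype TSV (individual_id breed phenotype) aligned to the dataset."""
    df = pd.read_csv(path, sep="\t").set_index("individual_id")
    missing = [i for i in dataset.individual_ids if i not in df.index]
    if missing:
        raise ValueError(f"phenotype file lacks {len(missing)} individuals "
                         f"(first: {missing[0]!r})")
    return df.loc[dataset.individual_ids, "phenotype"].to_numpy(float)


def merge_hit_report(assoc: dict[str, pd.DataFrame], window_het: pd.DataFrame,
                     maf_het: pd.DataFrame, s_table: pd.DataFrame,
                     dataset: GenotypeDataset,
                     fdr_threshold: float = 0.10) -> pd.DataFrame:
    """Join each GWAS-significant SNP with its window-level statistics.

    Columns: snp_id, chromosome, position_bp, breed, effect,
    increasing_allele, snp_fdr, window_hotelling_fdr, window_S,
    maf_ratio_fdr.  SNPs falling in skipped/unusable windows carry NaN for
    the affected column; a SNP in no window at all is a bookkeeping bug and
    raises.
    """
    snp_index = {s.snp_id: j for j, s in enumerate(dataset.snps)}
    win_rows = window_het.reset_index(drop=True)
    s_rows = s_table.reset_index(drop=True)
    maf_idx = maf_het.set_index("snp_id") if len(maf_het) else None
    records = []
    for breed, table in assoc.items():
        hits = table[table["fdr"].notna() & (table["fdr"] <= fdr_threshold)]
        for row in hits.itertuples(index=False):
            j = snp_index[row.snp_id]
            in_win = (win_rows["start"] <= j) & (j < win_rows["end"])
            if not in_win.any():
                raise RuntimeError(f"SNP {row.snp_id} not covered by any window")
            wrow = win_rows[in_win].iloc[0]
            s_in = (s_rows["start"] <= j) & (j < s_rows["end"])
            s_val = s_rows[s_in]["S"].iloc[0] if s_in.any() else np.nan
            snp = dataset.snps[j]
            inc_allele = snp.allele_a2 if row.effect >= 0 else snp.allele_a1
            maf_fdr = (maf_idx.loc[row.snp_id, "fdr"]
                       if maf_idx is not None and row.snp_id in maf_idx.index
                       else np.nan)
            records.append({
                "snp_id": row.snp_id, "chromosome": snp.chromosome,
                "position_bp": snp.position_bp, "breed": breed,
                "effect": row.effect, "increasing_allele": inc_allele,
                "snp_fdr": row.fdr,
                "window_hotelling_fdr": wrow["fdr"],
                "window_S": s_val,
                "maf_ratio_fdr": maf_fdr,
            })
    cols = ["snp_id", "chromosome", "position_bp", "breed", "effect",
            "increasing_allele", "snp_fdr", "window_hotelling_fdr",
            "window_S", "maf_ratio_fdr"]
    return pd.DataFrame.from_records(records, columns=cols)


def _load_inputs(config: PipelineConfig):
    """Dataset + phenotype (+ haplotype truth for simulated inputs)."""
    if config.genotype_prefix is not None:
        dataset = read_genotypes(config.genotype_prefix, config.genotype_format)
        if config.phenotype_file is None:
            raise ValueError("phenotype_file required with genotype input")
        y = read_phenotypes(config.phenotype_file, dataset)
        return dataset, y, None
    if config.scenario_name is None:
        raise ValueError("config needs a scenario_name or genotype_prefix")
    overrides = dict(config.scenario_overrides)
    overrides.setdefault("seed", config.seed)
    overrides["qtl_spec"] = tuple(tuple(q) for q in overrides.get(
        "qtl_spec", scenario(config.scenario_name).qtl_spec))
    sim = scenario(config.scenario_name, **overrides)
    dataset, y, truth = simulate_dataset(sim)
    return dataset, y, truth


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage, writing TSV outputs and a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format=_FLOAT_FMT)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageFailure(name, exc) from exc

    dataset, phenotype, truth = _stage("input", lambda: _load_inputs(config))

    def _qc():
        ds, report = qc_filter(dataset, config.maf_min, config.ind_call_rate_min)
        return ds, report
    ds, qc_report = _stage("qc", _qc)
    # keep phenotype and phased truth aligned with the QC-surviving panel
    kept_ind = np.isin(np.asarray(dataset.individual_ids),
                       np.asarray(ds.individual_ids))
    phenotype = np.asarray(phenotype, float)[kept_ind]
    haplotypes = None
    if truth is not None:
        kept_snp = np.isin(np.asarray([s.snp_id for s in dataset.snps]),
                           np.asarray([s.snp_id for s in ds.snps]))
        haplotypes = truth.haplotypes[kept_ind][:, :, kept_snp]
    _write(qc_report.to_frame(), "qc_report.tsv")

    windows = _stage("windows", lambda: make_windows(ds, config.window_size))

    assoc: dict[str, pd.DataFrame] = {}
    for breed in ("B", "F"):
        def _gwas(breed=breed):
            model = MixedModelGWAS.from_breed(ds, phenotype, breed,
                                              mode=config.gwas_mode)
            return model.fit().table
        assoc[breed] = _stage(f"gwas_{breed}", _gwas)
        _write(assoc[breed], f"assoc_{breed}.tsv")

    window_het = _stage("window_het", lambda: window_het_scan(
        ds, windows, k=config.k, formula=config.hotelling_formula))
    _write(window_het, "window_het.tsv")
    n_skipped = int((window_het["status"] == "SKIPPED").sum())
    if n_skipped:
        warnings.append(f"{n_skipped} windows skipped in the Hotelling scan")
    if bool(window_het["ridged"].any()):
        warnings.append("ridge fallback used for singular pooled covariance")

    maf_het = _stage("maf_het", lambda: maf_het_scan(ds))
    _write(maf_het, "maf_het.tsv")

    phase = config.phase_mode
    if phase == "known" and haplotypes is None:
        raise StageFailure("ld_s", ValueError(
            "phase_mode='known' needs simulated input with phased truth"))
    s_table = _stage("ld_s", lambda: s_scan(ds, windows, phase=phase,
                                            haplotypes=haplotypes))
    _write(s_table, "s_scan.tsv")

    decay = {}
    for breed in ("B", "F"):
        decay[breed] = _stage(f"ld_decay_{breed}", lambda breed=breed: ld_decay(
            ds, breed, max_pairs_per_bin=config.max_pairs_per_bin,
            phase=phase, seed=config.seed, haplotypes=haplotypes).table)
        _write(decay[breed], f"ld_decay_{breed}.tsv")

    hit_report = _stage("report", lambda: merge_hit_report(
        assoc, window_het, maf_het, s_table, ds,
        fdr_threshold=config.fdr_threshold))
    _write(hit_report, "hit_report.tsv")

    manifest = {
        "breedhet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_individuals": ds.n_individuals,
        "n_snps": ds.n_snps,
        "n_windows": len(windows),
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    config.save(out / "config.yaml")

    return PipelineResult(config=config, qc_report=qc_report.to_frame(),
                          assoc=assoc, window_het=window_het, maf_het=maf_het,
                          s_table=s_table, decay=decay, hit_report=hit_report,
                          manifest=manifest)
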