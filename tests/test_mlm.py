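import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breedhet import (MixedModelGWAS, SimulationConfig, bh_fdr, compute_grm,
                      correlate_breed_results, fit_null_mlm, significant_hits,
                      simulate_dataset, single_snp_scan)
from breedhet.grm import GRM

from conftest import make_dataset


def brute_force_bh(p):
    """O(n^2) step-up from the definition: q_(i) = min_{j>=i} p_(j) n / j."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_i, idx in enumerate(order):
        q[idx] = min(
            min(p[order[j]] * n / (j + 1) for j in range(rank_i, n)), 1.0)
    return q


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def test_bh_hand_example():
    q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04, 0.05]))
    assert np.allclose(q, 0.05)


def test_bh_single_p():
    assert bh_fdr(np.array([0.037]))[0] == pytest.approx(0.037)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                max_size=60))
def test_bh_matches_brute_force(ps):
    p = np.asarray(ps)
    assert np.max(np.abs(bh_fdr(p) - brute_force_bh(p))) < 1e-12


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bh_fdr(np.array([0.1, np.nan]))


# ---------------------------------------------------------------------------
# REML null model
# ---------------------------------------------------------------------------

def test_identity_grm_recovers_total_variance():
    rng = np.random.default_rng(0)
    y = rng.normal(2.0, 1.5, size=120)
    g = GRM(np.eye(120), [str(i) for i in range(120)], 1)
    vc = fit_null_mlm(y, g)
    # sigma_g^2 and sigma_e^2 are jointly unidentifiable when G = I,
    # but their sum must equal the sample variance
    assert vc.sigma2_g + vc.sigma2_e == pytest.approx(np.var(y, ddof=1), rel=1e-6)


def test_pure_noise_gives_low_heritability():
    cfg = SimulationConfig(n_breed_B=150, n_breed_F=150, n_chromosomes=1,
                           snps_per_chromosome=300, fst_B=1e-6, fst_F=1e-6,
                           shared_founders=True, seed=40)
    ds, _, _ = simulate_dataset(cfg)
    rng = np.random.default_rng(41)
    y = rng.normal(size=ds.n_individuals)
    vc = fit_null_mlm(y, compute_grm(ds))
    assert vc.heritability < 0.15


def test_h2_recovery_moderate_n():
    cfg = SimulationConfig(n_breed_B=300, n_breed_F=2, n_chromosomes=1,
                           snps_per_chromosome=400, h2=0.5, seed=42)
    ds, y, _ = simulate_dataset(cfg)
    sub = ds.subset(individuals=ds.breed_mask("B"))
    vc = fit_null_mlm(y[ds.breed_mask("B")], compute_grm(sub))
    assert vc.converged
    assert abs(vc.heritability - 0.5) < 0.2


def test_non_finite_phenotype_rejected():
    g = GRM(np.eye(5), list("abcde"), 1)
    with pytest.raises(ValueError):
        fit_null_mlm(np.array([1.0, 2.0, np.inf, 0.0, 1.0]), g)


# ---------------------------------------------------------------------------
# single-SNP scan
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gwas_panel():
    cfg = SimulationConfig(n_breed_B=200, n_breed_F=2, n_chromosomes=1,
                           snps_per_chromosome=150, h2=0.5, seed=50)
    ds, y, _ = simulate_dataset(cfg)
    mask = ds.breed_mask("B")
    sub = ds.subset(individuals=mask)
    return sub, y[mask], compute_grm(sub)


def test_zero_variance_snp_gets_na_row(gwas_panel):
    ds, y, _ = gwas_panel
    dos = ds.dosages.copy()
    dos[:, 3] = 1.0
    mono = make_dataset(dos, breeds=list(ds.breed_labels))
    table = single_snp_scan(mono, y, compute_grm(ds))
    assert np.isnan(table.loc[3, "p"]) and np.isnan(table.loc[3, "effect"])
    # every SNP with dosage variation is tested
    varying = np.nanstd(dos, axis=0) > 0
    assert table.loc[varying, "p"].notna().all()
    assert len(table) == mono.n_snps  # NA rows kept, not dropped


def test_affine_invariance_of_p_values(gwas_panel):
    ds, y, grm = gwas_panel
    t1 = single_snp_scan(ds, y, grm)
    t2 = single_snp_scan(ds, 3.7 * y - 11.0, grm)
    assert np.allclose(t1["p"], t2["p"], atol=1e-8, equal_nan=True)
    assert np.allclose(t2["effect"], 3.7 * t1["effect"], atol=1e-6,
                       equal_nan=True)


def test_exact_and_profile_modes_agree(gwas_panel):
    ds, y, grm = gwas_panel
    fast = single_snp_scan(ds, y, grm, mode="lrt-null-vc")
    exact = single_snp_scan(ds, y, grm, mode="lrt-exact")
    ok = fast["p"].notna()
    diff = np.abs(np.log10(fast.loc[ok, "p"]) - np.log10(exact.loc[ok, "p"]))
    assert np.mean(diff < 0.5) >= 0.95


def test_planted_qtl_found(gwas_panel):
    # plant a strong QTL on top of the simulated phenotype
    ds, y, grm = gwas_panel
    rng = np.random.default_rng(51)
    x = ds.dosages[:, 42]
    y_qtl = y + 0.8 * np.where(np.isnan(x), np.nanmean(x), x)
    table = single_snp_scan(ds, y_qtl, grm)
    assert table["p"].idxmin() == 42


def test_permuted_phenotype_type_one_error(gwas_panel):
    ds, y, grm = gwas_panel
    rng = np.random.default_rng(52)
    table = single_snp_scan(ds, rng.permutation(y), grm)
    rate = float((table["p"].dropna() < 0.05).mean())
    assert 0.01 < rate < 0.10  # coarse check; the fine band is in acceptance


# ---------------------------------------------------------------------------
# hits and cross-breed correlation
# ---------------------------------------------------------------------------

def test_significant_hits_boundary_inclusive():
    import pandas as pd
    tbl = pd.DataFrame({"snp_id": list("abc"), "p": [0.001, 0.002, 0.003],
                        "fdr": [0.05, 0.10, 0.11]})
    hits = significant_hits(tbl, 0.10)
    assert hits["snp_id"].tolist() == ["a", "b"]
    assert significant_hits(tbl.assign(fdr=1.0)).empty


def test_correlate_identical_tables(gwas_panel):
    ds, y, grm = gwas_panel
    t = single_snp_scan(ds, y, grm)
    out = correlate_breed_results(t, t, top_n=20)
    assert out["r_p_all"] == pytest.approx(1.0)
    assert out["r_effect_all"] == pytest.approx(1.0)
    assert out["r_p_top_B"] == pytest.approx(1.0)


def test_correlate_requires_shared_snps():
    import pandas as pd
    a = pd.DataFrame({"snp_id": ["x", "y"], "p": [0.1, 0.2],
                      "effect": [0.0, 0.1]})
    with pytest.raises(ValueError):
        correlate_breed_results(a, a.iloc[:1])


def test_independent_null_scans_uncorrelated():
    out = {}
    tables = {}
    for breed_seed in (60, 61):
        cfg = SimulationConfig(n_breed_B=120, n_breed_F=2, n_chromosomes=1,
                               snps_per_chromosome=800, seed=breed_seed)
        ds, y, _ = simulate_dataset(cfg)
        mask = ds.breed_mask("B")
        sub = ds.subset(individuals=mask)
        tables[breed_seed] = single_snp_scan(sub, y[mask], compute_grm(sub))
    res = correlate_breed_results(tables[60], tables[61])
    assert abs(res["r_p_all"]) < 0.1


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

def test_model_results_surface(gwas_panel):
    ds, y, grm = gwas_panel
    res = MixedModelGWAS(y, ds, grm=grm).fit()
    assert set(res.table.columns) >= {"snp_id", "effect", "lrt", "p", "fdr"}
    assert res.varcomp.sigma2_e > 0
    text = res.summary()
    assert "sigma2_g" in text and "h2 estimate" in text
    man = res.manhattan_data()
    assert man["cumulative_bp"].is_monotonic_increasing
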