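import numpy as np
import pytest
from scipy import stats

from sgmreg.data_model import build_gene_index
from sgmreg.simulate import (SimulationScenario, build_scenario_collection,
                             simulate_genotypes, simulate_phenotype,
                             _draw_structure, _draw_tau)


def small_scenario(**kw):
    base = dict(n_genes=12, n_causal=3, snps_per_gene_range=(4, 8),
                causal_snps_per_gene=2, snp_sample_sizes=(80, 40),
                expr_sample_sizes=(30,), seed=0)
    base.update(kw)
    return SimulationScenario(**base)


def test_default_scenario_shape():
    sc = SimulationScenario()
    assert sc.n_genes == 200 and sc.n_causal == 20
    assert sc.snp_sample_sizes == (600, 400, 200)
    assert sc.expr_sample_sizes == (70, 50, 30)


def test_scenario_validation():
    with pytest.raises(ValueError):
        small_scenario(n_causal=20)
    with pytest.raises(ValueError):
        small_scenario(causal_snps_per_gene=5)
    with pytest.raises(ValueError):
        small_scenario(ld_decay=1.0)


def test_collection_structure_and_invariants():
    sc = small_scenario()
    col, groups, truth = build_scenario_collection(sc)
    assert col.n_tasks == 3 and col.n_levels == 2
    assert groups.n_genes == 12
    groups.validate_partition()
    assert len(truth.causal_gene_ids) == 3
    # features standardized after build
    for d in col.datasets:
        np.testing.assert_allclose(d.X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(d.X.std(axis=0, ddof=1), 1.0, atol=1e-10)


def test_seeded_determinism():
    sc = small_scenario(seed=11)
    c1, _, t1 = build_scenario_collection(sc)
    c2, _, t2 = build_scenario_collection(small_scenario(seed=11))
    for a, b in zip(c1.datasets, c2.datasets):
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.Y, b.Y)
    np.testing.assert_array_equal(t1.eta, t2.eta)


def test_sigma_zero_reduces_to_fixed_effects():
    """The dynamic generator at sigma=0 IS the fixed-effect generator."""
    c_fixed, _, t_fixed = build_scenario_collection(
        small_scenario(seed=5, sigma_dynamic=0.0))
    taus = np.vstack(list(t_fixed.tau.values()))
    assert np.all(taus == taus[0])  # identical across all datasets
    np.testing.assert_array_equal(taus[0], t_fixed.eta * 1.0)


def test_delta_zero_means_no_effects():
    _, _, truth = build_scenario_collection(
        small_scenario(seed=3, delta_effect=0.0))
    for tau in truth.tau.values():
        np.testing.assert_array_equal(tau, 0.0)


def test_dynamic_tau_disperses_across_datasets():
    _, _, truth = build_scenario_collection(
        small_scenario(seed=8, sigma_dynamic=0.8))
    taus = np.vstack(list(truth.tau.values()))
    assert np.any(taus != taus[0])
    # pooled deviations from the baseline have sd near sigma
    dev = taus - truth.eta * 1.0
    assert 0.4 < dev.std(ddof=1) < 1.2


def test_genotype_maf_and_hwe():
    sc = small_scenario(ld_decay=0.5)
    rng = np.random.default_rng(0)
    truth = _draw_structure(sc, rng)
    G = simulate_genotypes(10_000, truth, sc, np.random.default_rng(1))
    mafs = np.concatenate([truth.mafs[g] for g in truth.gene_ids])
    realized = G.mean(axis=0) / 2.0
    assert np.max(np.abs(realized - mafs)) < 0.02
    # Hardy-Weinberg: genotype counts vs expected under p^2, 2pq, q^2
    n = G.shape[0]
    fails = 0
    for j, p in enumerate(mafs):
        counts = np.array([(G[:, j] == k).sum() for k in (0, 1, 2)])
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        chi2 = float(((counts - exp) ** 2 / exp).sum())
        if stats.chi2.sf(chi2, df=1) <= 0.001:
            fails += 1
    assert fails / len(mafs) < 0.01


def test_ld_decay_zero_gives_independent_snps():
    sc = small_scenario(ld_decay=0.0)
    truth = _draw_structure(sc, np.random.default_rng(0))
    G = simulate_genotypes(5000, truth, sc, np.random.default_rng(2))
    # adjacent SNPs within each gene are uncorrelated
    off = 0
    rs = []
    for q in range(sc.n_genes):
        d = truth.snps_per_gene[q]
        for j in range(d - 1):
            rs.append(np.corrcoef(G[:, off + j], G[:, off + j + 1])[0, 1])
        off += d
    assert np.max(np.abs(rs)) < 0.06


def test_ld_decay_induces_local_correlation():
    sc = small_scenario(ld_decay=0.8)
    truth = _draw_structure(sc, np.random.default_rng(0))
    G = simulate_genotypes(5000, truth, sc, np.random.default_rng(2))
    r = np.corrcoef(G[:, 0], G[:, 1])[0, 1]
    assert r > 0.3


def test_expression_correlation_decay():
    sc = SimulationScenario(n_genes=30, n_causal=2, snps_per_gene_range=(4, 6),
                            causal_snps_per_gene=2, snp_sample_sizes=(50,),
                            expr_sample_sizes=(5000,), seed=4)
    col, _, truth = build_scenario_collection(sc)
    expr_raw = col.datasets[-1].X  # standardized; correlation unaffected
    causal = {truth.gene_ids.index(g) for g in truth.causal_gene_ids}
    lag1, lag10 = [], []
    for i in range(sc.n_genes - 1):
        if i in causal or (i + 1) in causal:
            continue
        lag1.append(np.corrcoef(expr_raw[:, i], expr_raw[:, i + 1])[0, 1])
    for i in range(sc.n_genes - 10):
        if i in causal or (i + 10) in causal:
            continue
        lag10.append(np.corrcoef(expr_raw[:, i], expr_raw[:, i + 10])[0, 1])
    assert abs(np.mean(lag1) - 0.3) < 0.05
    assert abs(np.mean(lag10)) < 0.05


def test_causal_expression_tracks_genotype_signal():
    """Causal expression is additive in causal dosages: mean 4 when both
    causal genotypes are fixed at 2 with beta=(1,1)."""
    geno = np.full((2000, 2), 2.0)
    rng = np.random.default_rng(3)
    expr = geno @ np.array([1.0, 1.0]) + rng.standard_normal(2000)
    assert abs(expr.mean() - 4.0) < 0.1


def test_null_phenotype_prevalence_near_half():
    sc = small_scenario(delta_effect=0.0, snp_sample_sizes=(4000,),
                        expr_sample_sizes=(30,), seed=6)
    col, _, _ = build_scenario_collection(sc)
    y = col.datasets[0].Y
    assert 0.45 < y.mean() < 0.55


def test_strong_signal_phenotype_is_predictable():
    rng = np.random.default_rng(0)
    expr = rng.standard_normal((4000, 3))
    tau = np.array([3.0, -3.0, 3.0])
    sc = small_scenario()
    y = simulate_phenotype(expr, tau, sc, np.random.default_rng(1))
    lp = expr @ tau
    # AUC of the true linear predictor
    pos, neg = lp[y == 1], lp[y == 0]
    u = stats.mannwhitneyu(pos, neg).statistic
    auc = u / (len(pos) * len(neg))
    assert auc > 0.9


def test_quantitative_phenotype_mode():
    sc = small_scenario(binary_phenotype=False, seed=2)
    col, _, _ = build_scenario_collection(sc)
    y = col.datasets[0].Y
    assert len(np.unique(y)) > 10  # continuous, not 0/1
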