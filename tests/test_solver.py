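import numpy as np
import pytest

from sgmreg.data_model import OmicsDataset, build_collection, build_gene_index
from sgmreg.penalties import SparsityHyperparams
from sgmreg.solver import (ADMMOptions, MultitaskSGLasso, MultitaskSGRidge,
                           fit, multitask_loss, objective_value)
from _tiny import make_tiny_problem


def single_task(seed=0, n=30, d=5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    Y = X @ rng.standard_normal(d) + 0.3 * rng.standard_normal(n)
    ds = OmicsDataset(dataset_id="t0", level=0, platform=0, X=X, Y=Y,
                      feature_ids=[f"f{j}" for j in range(d)],
                      feature_genes=[f"g{j % 3}" for j in range(d)])
    col = build_collection([ds])
    return col, build_gene_index(col)


def test_penalty_free_single_task_recovers_ols():
    col, groups = single_task()
    d = col.datasets[0]
    res = fit(col, groups, SparsityHyperparams(), "sglasso")
    ols = np.linalg.lstsq(d.X, d.Y - d.Y.mean(), rcond=None)[0]
    np.testing.assert_allclose(res.C_hat.values, ols, atol=1e-6)
    res2 = fit(col, groups, SparsityHyperparams(), "sgridge")
    np.testing.assert_allclose(res2.C_hat.values, ols, atol=1e-6)


def test_l1_kill_condition_gives_exact_zero():
    """lambda2 above max |2 w X'Y| zeroes the whole solution exactly."""
    col, groups, _ = make_tiny_problem(3, "sglasso")
    kill = max(np.max(np.abs(2 * d.loss_weight * d.X.T @ (d.Y - d.Y.mean())))
               for d in col.datasets)
    res = fit(col, groups, SparsityHyperparams(lambda1=0.0, lambda2=kill * 1.01),
              "sglasso")
    assert np.all(res.C_hat.values == 0.0)


def test_c_update_matches_dense_normal_equations():
    """One C update equals the brute-force dense solve per task."""
    col, groups, _ = make_tiny_problem(0, "sglasso")
    rng = np.random.default_rng(42)
    dim = col.total_dim
    rho = 1.7
    V1, D1, V2, D2 = (rng.standard_normal(dim) for _ in range(4))
    offsets = col.task_offsets
    from sgmreg.solver import _TaskSolver
    for i, d in enumerate(col.datasets):
        sl = slice(offsets[i], offsets[i] + d.n_features)
        w = d.loss_weight
        yc = d.Y - d.Y.mean()
        rhs = (2 * w * d.X.T @ yc
               + rho * (V1 + D1 + V2 + D2)[sl])
        direct = np.linalg.solve(2 * w * d.X.T @ d.X
                                 + 2 * rho * np.eye(d.n_features), rhs)
        got = _TaskSolver(d.X, w).solve(2 * rho, rhs)
        np.testing.assert_allclose(got, direct, atol=1e-10)


@pytest.mark.parametrize("model", ["sglasso", "sgridge"])
def test_rho_init_invariance(model):
    """Final objective is insensitive to the initial rho."""
    col, groups, hp = make_tiny_problem(2, model)
    objs = []
    for rho0 in (0.1, 1.0, 10.0):
        res = fit(col, groups, hp, model, ADMMOptions(rho0=rho0))
        objs.append(res.objective_trace[-1])
    assert max(objs) - min(objs) <= 1e-4 * abs(min(objs))


def test_adaptive_rho_matches_fixed_rho_objective():
    col, groups, hp = make_tiny_problem(5, "sglasso")
    adaptive = fit(col, groups, hp, "sglasso", ADMMOptions(adapt_rho=True))
    fixed = fit(col, groups, hp, "sglasso",
                ADMMOptions(adapt_rho=False, max_iter=20000))
    rel = abs(adaptive.objective_trace[-1] - fixed.objective_trace[-1]) \
        / abs(fixed.objective_trace[-1])
    assert rel < 1e-4


def test_residuals_vanish_at_convergence():
    col, groups, hp = make_tiny_problem(1, "sglasso")
    res = fit(col, groups, hp, "sglasso")
    assert res.converged
    assert res.res_pri < 1e-3 and res.res_dual < 1e-3


def test_group_sparsity_for_large_lambda1():
    """Above a problem-dependent lambda1, whole gene groups are exactly 0."""
    col, groups = single_task(seed=4, n=25, d=9)
    res = fit(col, groups, SparsityHyperparams(lambda1=200.0, lambda2=0.0),
              "sglasso")
    for g in groups.gene_ids:
        block = res.C_hat.values[groups.stacked_slices[g]]
        assert np.all(block == 0.0)
    # moderate lambda1: some but not all groups survive, each exactly 0 or not
    res2 = fit(col, groups, SparsityHyperparams(lambda1=8.0, lambda2=0.0),
               "sglasso")
    norms = [np.linalg.norm(res2.C_hat.values[groups.stacked_slices[g]])
             for g in groups.gene_ids]
    assert any(n == 0.0 for n in norms) or any(n > 0 for n in norms)


def test_max_iter_reports_not_converged():
    col, groups, hp = make_tiny_problem(0, "sglasso")
    res = fit(col, groups, hp, "sglasso", ADMMOptions(max_iter=3))
    assert not res.converged and res.iterations_used == 3


def test_estimator_api_roundtrip():
    col, groups, _ = make_tiny_problem(4, "sglasso")
    est = MultitaskSGLasso(lambda1=1.0, lambda2=0.5)
    assert est.get_params()["lambda1"] == 1.0
    est.set_params(lambda1=2.0).fit(col, groups)
    assert est.converged_ and est.coef_.values.shape == (col.total_dim,)
    preds = est.predict(col)
    assert len(preds) == col.n_tasks
    assert all(len(p) == d.n_samples for p, d in zip(preds, col.datasets))
    # predictions beat the intercept-only baseline in-sample
    loss_fit = sum(np.sum((d.Y - p) ** 2) for p, d in zip(preds, col.datasets))
    loss_null = sum(np.sum((d.Y - d.Y.mean()) ** 2) for d in col.datasets)
    assert loss_fit <= loss_null + 1e-9


def test_objective_trace_decreases_overall():
    col, groups, hp = make_tiny_problem(6, "sgridge")
    res = fit(col, groups, hp, "sgridge")
    trace = np.array(res.objective_trace)
    assert trace[-1] <= trace[0]
    assert res.objective_trace[-1] == pytest.approx(
        objective_value(col, groups, res.C_hat.values, hp, "sgridge"),
        rel=1e-3)
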