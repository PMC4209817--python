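"""Gene-level association test with a pooled permutation null.

The fitted stacked coefficients are summarized per gene as
``S_i = sum_j ||C_i^(j)||_2^2`` (sum over tasks of squared l2 norms of
the gene's coefficient sub-vectors).  Because genes contain different
numbers of features, raw ``S`` values are not comparable across genes;
each gene's statistic is standardized by the mean and standard deviation
of its own permutation null::

    S~_i = (S_i - mean(S0_i)) / sd(S0_i)

Phenotypes are permuted independently within every dataset (subjects are
disjoint across studies), the model is refit at the hyperparameters
selected by cross-validation on the unpermuted data, and the
standardized null draws of all genes are pooled into one empirical null
set, against which each observed ``S~_i`` is ranked:
``p_i = #{null >= S~_i} / #null``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CoefficientStack, GeneGroupIndex, StudyCollection
from .model_selection import make_cv_plan, cross_validate
from .penalties import SparsityHyperparams
from .solver import ADMMOptions, fit as admm_fit

logger = logging.getLogger(__name__)

__all__ = ["GeneTestResult", "PermutationNull", "gene_statistic",
           "permutation_null", "empirical_pvalue", "run_gene_test",
           "GenePermutationTest"]


@dataclass
class GeneTestResult:
    gene_id: str
    S_hat: float
    S_null_mean: float
    S_null_sd: float
    S_tilde: float
    p_value: float
    B: int


@dataclass
class PermutationNull:
    """Per-gene standardized null draws and the pooled null set."""

    gene_ids: list[str]
    raw_draws: np.ndarray        # (B, Q) unstandardized S values
    null_means: np.ndarray       # (Q,)
    null_sds: np.ndarray         # (Q,) ddof=1; 0 flags a degenerate gene
    standardized: np.ndarray     # (B, Q); zero where degenerate
    pooled: np.ndarray           # flattened standardized draws
    seed: int


def gene_statistic(C_hat: CoefficientStack, groups: GeneGroupIndex) -> np.ndarray:
    """Per-gene statistic: sum over tasks of squared l2 norms.

    Since the gene groups are disjoint and their stacked indices
    concatenate the per-task sub-vectors, this equals the squared l2
    norm of the gene's slice of the stacked vector.
    """
    return np.array([
        float(C_hat.values[groups.stacked_slices[g]] @
              C_hat.values[groups.stacked_slices[g]])
        for g in groups.gene_ids])


def _permuted_collection(collection: StudyCollection,
                         rng: np.random.Generator) -> StudyCollection:
    import copy
    permuted = []
    for d in collection.datasets:
        pd_ = copy.copy(d)
        pd_.Y = d.Y[rng.permutation(d.n_samples)]
        permuted.append(pd_)
    return StudyCollection(permuted)


def permutation_null(collection: StudyCollection, groups: GeneGroupIndex,
                     hyperparams: SparsityHyperparams, model_tag: str,
                     B: int, seed: int,
                     options: ADMMOptions | None = None) -> PermutationNull:
    """B phenotype-permutation refits at frozen hyperparameters."""
    if B < 2:
        raise ValueError("need at least 2 permutations to estimate a null sd")
    options = options or ADMMOptions()
    rng = np.random.default_rng(seed)
    Q = groups.n_genes
    draws = np.empty((B, Q))
    cache: dict = {}  # X is unchanged across permutations; reuse SVDs
    for b in range(B):
        perm = _permuted_collection(collection, rng)
        res = admm_fit(perm, groups, hyperparams, model_tag, options,
                       solver_cache=cache)
        draws[b] = gene_statistic(res.C_hat, groups)
    means = draws.mean(axis=0)
    sds = draws.std(axis=0, ddof=1)
    degenerate = sds <= 0
    if degenerate.any():
        logger.warning("%d gene(s) have a constant permutation statistic; "
                       "their p-values are set to 1", int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, sds)
    standardized = (draws - means) / safe
    standardized[:, degenerate] = 0.0
    pooled = standardized[:, ~degenerate].ravel() if (~degenerate).any() \
        else np.empty(0)
    return PermutationNull(gene_ids=list(groups.gene_ids), raw_draws=draws,
                           null_means=means, null_sds=sds,
                           standardized=standardized, pooled=pooled, seed=seed)


def empirical_pvalue(S_tilde: float, pooled_null: np.ndarray,
                     smooth: bool = False) -> float:
    """Empirical tail probability against the pooled null.

    ``p = #{null >= S~} / #null``; with ``smooth`` the add-one version
    ``(1 + #{null >= S~}) / (1 + #null)`` guarantees a nonzero p.
    """
    pooled_null = np.asarray(pooled_null, dtype=float)
    if pooled_null.size == 0:
        raise ValueError("pooled null is empty")
    count = int(np.sum(pooled_null >= S_tilde))
    if smooth:
        return (1 + count) / (1 + pooled_null.size)
    return count / pooled_null.size


def run_gene_test(collection: StudyCollection, groups: GeneGroupIndex,
                  model_tag: str = "sglasso", n_folds: int = 5,
                  grid_size: int = 30, B: int = 500, seed: int = 0,
                  smooth: bool = False, options: ADMMOptions | None = None,
                  hyperparams: dict | None = None) -> pd.DataFrame:
    """Full pipeline: CV, full-data fit, permutation null, p-values.

    ``hyperparams`` skips cross-validation when supplied.  Returns a tidy
    DataFrame sorted as in ``groups.gene_ids``.
    """
    options = options or ADMMOptions()
    if hyperparams is None:
        plan = make_cv_plan(collection, model_tag, n_folds, grid_size, seed)
        hyperparams, _ = cross_validate(collection, groups, model_tag, plan,
                                        options)
    hp = SparsityHyperparams(**hyperparams, rho=options.rho0)
    full = admm_fit(collection, groups, hp, model_tag, options)
    S_hat = gene_statistic(full.C_hat, groups)

    null = permutation_null(collection, groups, hp, model_tag, B, seed,
                            options)
    degenerate = null.null_sds <= 0
    S_tilde = np.where(degenerate, 0.0,
                       (S_hat - null.null_means)
                       / np.where(degenerate, 1.0, null.null_sds))
    pooled_sorted = np.sort(null.pooled) if null.pooled.size else null.pooled
    pvals = np.empty(groups.n_genes)
    for i in range(groups.n_genes):
        if degenerate[i]:
            pvals[i] = 1.0
        else:
            count = pooled_sorted.size - int(
                np.searchsorted(pooled_sorted, S_tilde[i], side="left"))
            if smooth:
                pvals[i] = (1 + count) / (1 + pooled_sorted.size)
            else:
                pvals[i] = count / pooled_sorted.size
    n_feats = [sum(len(groups.membership.get((g, d.dataset_id), ()))
                   for d in collection.datasets) for g in groups.gene_ids]
    return pd.DataFrame({
        "gene_id": groups.gene_ids, "S_hat": S_hat,
        "S_null_mean": null.null_means, "S_null_sd": null.null_sds,
        "S_tilde": S_tilde, "p_value": pvals, "n_features": n_feats,
        "B": B})


class GenePermutationTest:
    """Estimator-style wrapper around :func:`run_gene_test`.

    Parameters mirror the pipeline stages; after ``fit`` the per-gene
    table is in ``results_`` and the selected penalties in
    ``hyperparams_``.
    """

    def __init__(self, model: str = "sglasso", n_folds: int = 5,
                 grid_size: int = 30, B: int = 500, seed: int = 0,
                 smooth: bool = False, hyperparams: dict | None = None,
                 options: ADMMOptions | None = None):
        self.model = model
        self.n_folds = n_folds
        self.grid_size = grid_size
        self.B = B
        self.seed = seed
        self.smooth = smooth
        self.hyperparams = hyperparams
        self.options = options

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("model", "n_folds", "grid_size", "B", "seed", "smooth",
                 "hyperparams", "options")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, collection: StudyCollection, groups: GeneGroupIndex):
        hp = self.hyperparams
        if hp is None:
            plan = make_cv_plan(collection, self.model, self.n_folds,
                                self.grid_size, self.seed)
            hp, surface = cross_validate(collection, groups, self.model, plan,
                                         self.options or ADMMOptions())
            self.cv_results_ = surface
        self.hyperparams_ = hp
        self.results_ = run_gene_test(
            collection, groups, model_tag=self.model, B=self.B,
            seed=self.seed, smooth=self.smooth, options=self.options,
            hyperparams=hp)
        return self
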