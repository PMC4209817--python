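"""Multi-study SNP + expression + phenotype simulator.

Emulates a two-level multi-omics design: several SNP genotype studies
and several gene-expression studies, all with disjoint subjects, sharing
one gene universe and one set of causal genes.

Genotypes come from a latent-Gaussian haplotype surrogate: per subject,
two independent haplotype vectors are drawn from a within-gene AR(1)
Gaussian (parameter ``ld_decay``) and thresholded at each SNP's minor
allele frequency quantile; the 0/1/2 genotype is their sum.  Hardy-
Weinberg equilibrium holds by construction (haplotypes are independent)
and local LD decays geometrically within a gene.

Causal-gene expression is additive in that study's causal SNP dosages,
``G_i = sum_j SNP_causal_j * beta_j + eps`` with ``eps ~ N(0,1)``;
non-causal genes are jointly Gaussian with correlation ``0.3^|i-j|`` in
gene order.  The binary phenotype follows a logistic model on the causal
expression, ``logit Pr(Y=1) = sum_j G_causal_j * tau_j + eps'`` with
``eps' ~ N(0,1)``; SNP-only studies first generate latent causal
expression from their own genotypes and discard it after drawing ``Y``.

Effect sizes: a baseline ``eta_j`` per causal gene (uniform magnitude in
[0.2, 2], random sign) scaled by ``delta_effect``; under the dynamic
model each dataset additionally perturbs the effects,
``tau_j ~ N(eta_j * delta_effect, sigma_dynamic^2)``.  With
``sigma_dynamic = 0`` no perturbation is drawn, so the dynamic model
reduces exactly (bitwise) to the fixed-effect one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtri

from .data_model import (GeneGroupIndex, OmicsDataset, StudyCollection,
                         build_collection, build_gene_index)

__all__ = ["SimulationScenario", "GenerativeTruth", "simulate_genotypes",
           "simulate_expression", "simulate_phenotype",
           "build_scenario_collection"]


@dataclass
class SimulationScenario:
    """All generative parameters of one simulated study design."""

    n_genes: int = 200
    n_causal: int = 20
    snps_per_gene_range: tuple[int, int] = (10, 100)
    causal_snps_per_gene: int = 2
    causal_maf_range: tuple[float, float] = (0.15, 0.25)
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_sample_sizes: tuple[int, ...] = (600, 400, 200)
    expr_sample_sizes: tuple[int, ...] = (70, 50, 30)
    beta_range: tuple[float, float] = (1.0, 1.2)
    eta_magnitude_range: tuple[float, float] = (0.2, 2.0)
    delta_effect: float = 1.0
    sigma_dynamic: float = 0.0
    expr_corr_base: float = 0.3
    ld_decay: float = 0.8
    binary_phenotype: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_genes:
            raise ValueError("more causal genes than genes")
        if self.causal_snps_per_gene > self.snps_per_gene_range[0]:
            raise ValueError("causal SNPs per gene exceed minimum gene size")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")
        if not (self.maf_range[0] >= 0.0 and self.maf_range[1] <= 0.5):
            raise ValueError("MAF range must lie within (0, 0.5]")


@dataclass
class GenerativeTruth:
    """Everything the generator decided: the answer key for evaluation."""

    gene_ids: list[str]
    causal_gene_ids: list[str]
    snps_per_gene: np.ndarray
    mafs: dict[str, np.ndarray]              # gene -> per-SNP MAF
    causal_snp_positions: dict[str, np.ndarray]
    betas: dict[str, np.ndarray]             # causal gene -> per-causal-SNP beta
    eta: np.ndarray                          # baseline effects, length n_causal
    tau: dict[str, np.ndarray]               # dataset_id -> per-causal-gene tau


def _draw_structure(scenario: SimulationScenario,
                    rng: np.random.Generator) -> GenerativeTruth:
    Q, m = scenario.n_genes, scenario.n_causal
    gene_ids = [f"G{q:04d}" for q in range(Q)]
    lo, hi = scenario.snps_per_gene_range
    snps_per_gene = rng.integers(lo, hi + 1, size=Q)
    causal = sorted(rng.choice(Q, size=m, replace=False).tolist())
    causal_ids = [gene_ids[q] for q in causal]
    mafs, causal_pos, betas = {}, {}, {}
    for q, g in enumerate(gene_ids):
        maf = rng.uniform(*scenario.maf_range, size=snps_per_gene[q])
        if g in causal_ids:
            pos = np.sort(rng.choice(snps_per_gene[q],
                                     size=scenario.causal_snps_per_gene,
                                     replace=False))
            maf[pos] = rng.uniform(*scenario.causal_maf_range, size=len(pos))
            causal_pos[g] = pos
            betas[g] = rng.uniform(*scenario.beta_range, size=len(pos))
        mafs[g] = maf
    sign = rng.choice([-1.0, 1.0], size=m)
    eta = sign * rng.uniform(*scenario.eta_magnitude_range, size=m)
    return GenerativeTruth(gene_ids=gene_ids, causal_gene_ids=causal_ids,
                           snps_per_gene=snps_per_gene, mafs=mafs,
                           causal_snp_positions=causal_pos, betas=betas,
                           eta=eta, tau={})


def _ar1_normal(n: int, d: int, phi: float,
                rng: np.random.Generator) -> np.ndarray:
    """n draws of a d-dimensional AR(1) standard Gaussian, corr phi^|i-j|."""
    z = rng.standard_normal((n, d))
    if phi == 0 or d == 1:
        return z
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    scale = np.sqrt(1.0 - phi * phi)
    for j in range(1, d):
        out[:, j] = phi * out[:, j - 1] + scale * z[:, j]
    return out


def simulate_genotypes(n: int, truth: GenerativeTruth,
                       scenario: SimulationScenario,
                       rng: np.random.Generator) -> np.ndarray:
    """0/1/2 genotypes for all genes' SNPs of ``n`` subjects.

    Two latent haplotypes per subject with within-gene AR(1) correlation
    ``ld_decay``, thresholded at each SNP's MAF quantile and summed.
    Columns follow gene order, ``truth.snps_per_gene[q]`` columns each.
    A column that comes out constant (possible at small ``n`` for rare
    alleles) is redrawn so downstream standardization is well defined.
    """
    blocks = []
    for g in truth.gene_ids:
        maf = truth.mafs[g]
        cut = ndtri(maf)
        h1 = _ar1_normal(n, len(maf), scenario.ld_decay, rng)
        h2 = _ar1_normal(n, len(maf), scenario.ld_decay, rng)
        geno = (h1 < cut).astype(np.int8) + (h2 < cut).astype(np.int8)
        for _ in range(20):
            const = geno.min(axis=0) == geno.max(axis=0)
            if not const.any():
                break
            cols = np.flatnonzero(const)
            a = rng.standard_normal((n, len(cols)))
            b = rng.standard_normal((n, len(cols)))
            geno[:, cols] = ((a < cut[cols]).astype(np.int8)
                             + (b < cut[cols]).astype(np.int8))
        blocks.append(geno)
    return np.concatenate(blocks, axis=1).astype(float)


def _causal_expression(genotypes: np.ndarray, truth: GenerativeTruth,
                       rng: np.random.Generator) -> np.ndarray:
    """Additive causal expression from each causal gene's own SNPs."""
    offsets = np.concatenate([[0], np.cumsum(truth.snps_per_gene)[:-1]])
    gene_pos = {g: int(offsets[q]) for q, g in enumerate(truth.gene_ids)}
    n = genotypes.shape[0]
    expr = np.empty((n, len(truth.causal_gene_ids)))
    for j, g in enumerate(truth.causal_gene_ids):
        cols = gene_pos[g] + truth.causal_snp_positions[g]
        expr[:, j] = genotypes[:, cols] @ truth.betas[g] \
            + rng.standard_normal(n)
    return expr


def simulate_expression(genotypes: np.ndarray, truth: GenerativeTruth,
                        scenario: SimulationScenario,
                        rng: np.random.Generator) -> np.ndarray:
    """Expression matrix (samples x genes) for one expression study.

    Causal columns are additive in the study's causal SNP dosages with
    N(0,1) noise; all other columns are jointly Gaussian with
    correlation ``expr_corr_base^|i-j|`` in gene order.
    """
    n = genotypes.shape[0]
    expr = _ar1_normal(n, scenario.n_genes, scenario.expr_corr_base, rng)
    causal_expr = _causal_expression(genotypes, truth, rng)
    causal_idx = [truth.gene_ids.index(g) for g in truth.causal_gene_ids]
    expr[:, causal_idx] = causal_expr
    return expr


def simulate_phenotype(causal_expression: np.ndarray, tau: np.ndarray,
                       scenario: SimulationScenario,
                       rng: np.random.Generator) -> np.ndarray:
    """Phenotype from causal-gene expression.

    Binary: ``Y ~ Bernoulli(sigmoid(G_causal @ tau + eps'))`` with
    ``eps' ~ N(0,1)``; quantitative: the linear predictor plus the same
    Gaussian noise.
    """
    n = causal_expression.shape[0]
    lp = causal_expression @ tau + rng.standard_normal(n)
    if scenario.binary_phenotype:
        return (rng.uniform(size=n) < expit(lp)).astype(float)
    return lp


def _draw_tau(truth: GenerativeTruth, scenario: SimulationScenario,
              rng: np.random.Generator) -> np.ndarray:
    base = truth.eta * scenario.delta_effect
    if scenario.sigma_dynamic == 0:
        return base.copy()   # fixed-effect model: no extra draws consumed
    return rng.normal(base, scenario.sigma_dynamic)


def build_scenario_collection(scenario: SimulationScenario):
    """Generate the full multi-study design.

    Returns ``(StudyCollection, GeneGroupIndex, GenerativeTruth)``: one
    SNP dataset per entry of ``snp_sample_sizes`` (features = all SNPs,
    annotated to their genes) and one expression dataset per entry of
    ``expr_sample_sizes`` (one feature per gene).  Each dataset draws its
    own subjects; per-dataset random streams are spawned deterministically
    from the scenario seed.
    """
    root = np.random.SeedSequence(scenario.seed)
    ss_structure, ss_tau, ss_data = root.spawn(3)
    truth = _draw_structure(scenario, np.random.default_rng(ss_structure))
    tau_rng = np.random.default_rng(ss_tau)

    snp_feature_ids, snp_feature_genes = [], []
    for q, g in enumerate(truth.gene_ids):
        for k in range(truth.snps_per_gene[q]):
            snp_feature_ids.append(f"{g}_snp{k:03d}")
            snp_feature_genes.append(g)

    n_datasets = len(scenario.snp_sample_sizes) + len(scenario.expr_sample_sizes)
    data_streams = ss_data.spawn(n_datasets)
    datasets = []
    si = 0
    for p, n in enumerate(scenario.snp_sample_sizes):
        rng = np.random.default_rng(data_streams[si]); si += 1
        did = f"snp{p}"
        tau = _draw_tau(truth, scenario, tau_rng)
        truth.tau[did] = tau
        geno = simulate_genotypes(n, truth, scenario, rng)
        latent = _causal_expression(geno, truth, rng)
        Y = simulate_phenotype(latent, tau, scenario, rng)
        datasets.append(OmicsDataset(
            dataset_id=did, level=0, platform=p, X=geno, Y=Y,
            feature_ids=list(snp_feature_ids),
            feature_genes=list(snp_feature_genes)))
    for p, n in enumerate(scenario.expr_sample_sizes):
        rng = np.random.default_rng(data_streams[si]); si += 1
        did = f"expr{p}"
        tau = _draw_tau(truth, scenario, tau_rng)
        truth.tau[did] = tau
        geno = simulate_genotypes(n, truth, scenario, rng)
        expr = simulate_expression(geno, truth, scenario, rng)
        causal_idx = [truth.gene_ids.index(g) for g in truth.causal_gene_ids]
        Y = simulate_phenotype(expr[:, causal_idx], tau, scenario, rng)
        datasets.append(OmicsDataset(
            dataset_id=did, level=1, platform=p, X=expr, Y=Y,
            feature_ids=[f"{g}_expr" for g in truth.gene_ids],
            feature_genes=list(truth.gene_ids)))
    collection = build_collection(datasets)
    groups = build_gene_index(collection)
    return collection, groups, truth
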