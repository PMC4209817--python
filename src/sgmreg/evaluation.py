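"""Meta-analysis baseline, ROC/power computation, comparison harness.

The baseline is a sample-size-weighted z-score meta-analysis in the
style of METAL: per study, each feature gets a signed z from the score
test of the simple linear regression of the phenotype on that single
standardized feature; z-scores are combined across studies with weights
``sqrt(n_j)``; a gene is represented by its most significant feature
(min-p, uncorrected — the conventional usage, which is anticonservative
as a gene-level p-value and is only used for ranking here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneGroupIndex, StudyCollection
from .gene_test import run_gene_test
from .simulate import SimulationScenario, build_scenario_collection
from .solver import ADMMOptions

__all__ = ["ROCResult", "meta_analysis", "roc_curve", "run_comparison",
           "METHOD_TAGS"]

METHOD_TAGS = ("multitask-sglasso", "multitask-sgridge", "meta-SNP", "meta-EXP")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _feature_z(x: np.ndarray, y: np.ndarray) -> float:
    """Signed score-test z for the simple regression of y on one feature."""
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        return 0.0
    r = float(xc @ yc) / (sx * sy)
    r = np.clip(r, -0.999999999, 0.999999999)
    return r * np.sqrt(n)


def meta_analysis(collection: StudyCollection,
                  groups: GeneGroupIndex) -> pd.DataFrame:
    """Weighted-z meta-analysis with a min-p gene summary.

    Per feature id, signed z-scores from each study containing it are
    combined as ``Z = sum(sqrt(n_j) z_j) / sqrt(sum n_j)`` and converted
    to a two-sided p; the gene p is the minimum over its features.
    Returns a DataFrame (gene_id, p_value, best_feature).
    """
    per_feature: dict[str, list[tuple[float, int]]] = {}
    feature_gene: dict[str, str] = {}
    for d in collection.datasets:
        for j, (f, g) in enumerate(zip(d.feature_ids, d.feature_genes)):
            z = _feature_z(d.X[:, j], d.Y)
            per_feature.setdefault(f, []).append((z, d.n_samples))
            feature_gene[f] = g
    rows = []
    for f, zs in per_feature.items():
        w = np.sqrt([n for _, n in zs])
        z = np.array([z for z, _ in zs])
        Z = float((w * z).sum() / np.sqrt((w ** 2).sum()))
        p = 2.0 * stats.norm.sf(abs(Z))
        rows.append((f, feature_gene[f], Z, p))
    feat = pd.DataFrame(rows, columns=["feature_id", "gene_id", "Z", "p"])
    idx = feat.groupby("gene_id")["p"].idxmin()
    out = feat.loc[idx, ["gene_id", "p", "feature_id"]].rename(
        columns={"p": "p_value", "feature_id": "best_feature"})
    return out.reset_index(drop=True)


def roc_curve(p_values: np.ndarray, is_causal: np.ndarray,
              thresholds: np.ndarray | None = None) -> ROCResult:
    """ROC over p-value cutoffs.

    At cutoff ``t``: TPR = fraction of causal genes with ``p <= t``,
    FPR = same for non-causal genes.  ``thresholds`` defaults to the
    observed p-values plus the endpoints 0 and 1 (the exhaustive sweep);
    AUC is the trapezoid area under the swept curve closed at (0,0) and
    (1,1).
    """
    p = np.asarray(p_values, dtype=float)
    truth = np.asarray(is_causal, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("need both causal and non-causal genes")
    if thresholds is None:
        thresholds = np.unique(np.concatenate([p, [0.0, 1.0]]))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    tpr = np.array([(p[truth] <= t).mean() for t in thresholds])
    fpr = np.array([(p[~truth] <= t).mean() for t in thresholds])
    fx = np.concatenate([[0.0], fpr, [1.0]])
    fy = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(fy, fx))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def plot_roc(results: list[tuple[str, ROCResult]], out_path=None):
    """Plot labelled ROC curves; returns the matplotlib figure.

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, roc in results:
        fx = np.concatenate([[0.0], roc.fpr, [1.0]])
        fy = np.concatenate([[0.0], roc.tpr, [1.0]])
        ax.plot(fx, fy, label=f"{label} (AUC {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig


_SUBSETS = {"SNP-only": 0, "EXP-only": 1, "all": None}


def _method_pvalues(method: str, subset: str, collection: StudyCollection,
                    groups: GeneGroupIndex, *, grid_size: int, B: int,
                    n_folds: int, seed: int,
                    options: ADMMOptions | None) -> pd.Series:
    from .data_model import build_gene_index
    level = _SUBSETS[subset]
    sub = collection if level is None else collection.subset(level=level)
    sub_groups = build_gene_index(sub)
    if method.startswith("meta"):
        res = meta_analysis(sub, sub_groups)
        return res.set_index("gene_id")["p_value"]
    model = "sglasso" if method.endswith("sglasso") else "sgridge"
    res = run_gene_test(sub, sub_groups, model_tag=model, n_folds=n_folds,
                        grid_size=grid_size, B=B, seed=seed, options=options)
    return res.set_index("gene_id")["p_value"]


def run_comparison(scenario: SimulationScenario,
                   delta_grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                   sigma_grid=(0.0,), replicates: int = 50,
                   methods: dict[str, str] | None = None,
                   grid_size: int = 30, B: int = 500, n_folds: int = 5,
                   seed: int = 0,
                   options: ADMMOptions | None = None):
    """Simulate, run each method, and tabulate per-gene p-values and AUC.

    ``methods`` maps a label to ``(method_tag, subset)`` pairs encoded as
    ``"tag:subset"`` with subset in {SNP-only, EXP-only, all}; the
    default is the full eight-case comparison.  Returns
    ``(per_gene: DataFrame, summary: DataFrame)``; the summary holds the
    per-scenario mean and sd of AUC across replicates.
    """
    if methods is None:
        methods = {
            "sglasso-all": "multitask-sglasso:all",
            "sglasso-SNP": "multitask-sglasso:SNP-only",
            "sglasso-EXP": "multitask-sglasso:EXP-only",
            "sgridge-all": "multitask-sgridge:all",
            "sgridge-SNP": "multitask-sgridge:SNP-only",
            "sgridge-EXP": "multitask-sgridge:EXP-only",
            "meta-SNP": "meta-SNP:SNP-only",
            "meta-EXP": "meta-EXP:EXP-only",
        }
    rows, aucs = [], []
    rep_seeds = np.random.SeedSequence(seed).generate_state(
        len(delta_grid) * len(sigma_grid) * replicates) % (2 ** 31)
    k = 0
    from dataclasses import replace
    for sigma in sigma_grid:
        for delta in delta_grid:
            for rep in range(replicates):
                rep_seed = int(rep_seeds[k]); k += 1
                sc = replace(scenario, delta_effect=float(delta),
                             sigma_dynamic=float(sigma), seed=rep_seed)
                collection, groups, truth = build_scenario_collection(sc)
                causal = pd.Series(
                    [g in set(truth.causal_gene_ids) for g in groups.gene_ids],
                    index=groups.gene_ids)
                for label, spec_str in methods.items():
                    tag, subset = spec_str.split(":")
                    pvals = _method_pvalues(
                        tag, subset, collection, groups, grid_size=grid_size,
                        B=B, n_folds=n_folds, seed=rep_seed, options=options)
                    pvals = pvals.reindex(groups.gene_ids).fillna(1.0)
                    auc = roc_curve(pvals.to_numpy(),
                                    causal.to_numpy()).auc
                    aucs.append((sigma, delta, rep, label, auc))
                    for g in groups.gene_ids:
                        rows.append((sigma, delta, rep, label, g,
                                     float(pvals[g]), bool(causal[g])))
    per_gene = pd.DataFrame(rows, columns=[
        "sigma", "delta", "replicate", "method", "gene_id", "p_value",
        "is_causal"])
    auc_df = pd.DataFrame(aucs, columns=[
        "sigma", "delta", "replicate", "method", "auc"])
    summary = auc_df.groupby(["sigma", "delta", "method"])["auc"] \
        .agg(["mean", "std"]).reset_index() \
        .rename(columns={"mean": "auc_mean", "std": "auc_sd"})
    return per_gene, summary
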