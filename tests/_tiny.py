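"""Seeded tiny multitask problems used by solver oracle tests.

The generator is deliberately self-contained so the same problems can be
reproduced exactly outside the test suite (e.g. to recompute reference
optima with a general-purpose conic solver).
"""

from __future__ import annotations

import numpy as np

from sgmreg.data_model import (OmicsDataset, build_collection,
                               build_gene_index)
from sgmreg.penalties import SparsityHyperparams


def make_tiny_problem(seed: int, model: str):
    """One random 3-task, 6-gene problem (d_i <= 12, n_i <= 25).

    Tasks 0 and 1 sit at one omics level, task 2 at another, so both the
    level and the platform weighting paths are exercised.  Returns
    ``(collection, groups, hyperparams)``.
    """
    rng = np.random.default_rng(seed)
    Q = 6
    datasets = []
    for t in range(3):
        n = int(rng.integers(15, 26))
        d = int(rng.integers(7, 13))
        X = rng.standard_normal((n, d))
        beta = np.where(rng.uniform(size=d) < 0.4,
                        rng.standard_normal(d), 0.0)
        Y = X @ beta + 0.5 * rng.standard_normal(n)
        genes = rng.integers(0, Q, size=d)
        datasets.append(OmicsDataset(
            dataset_id=f"t{t}", level=0 if t < 2 else 1, platform=t,
            X=X, Y=Y,
            feature_ids=[f"t{t}_f{j}" for j in range(d)],
            feature_genes=[f"g{int(q)}" for q in genes]))
    collection = build_collection(datasets)
    groups = build_gene_index(collection)
    if model == "sglasso":
        hp = SparsityHyperparams(lambda1=float(rng.uniform(0.5, 4.0)),
                                 lambda2=float(rng.uniform(0.2, 2.0)))
    else:
        hp = SparsityHyperparams(lam=float(rng.uniform(0.05, 1.0)))
    return collection, groups, hp
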