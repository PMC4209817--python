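"""Proximal operators and penalty values for the two composite penalties.

Two bi-level sparsity penalties over the stacked coefficient vector are
supported, with genes as the (non-overlapping) groups:

* sparse group lasso: ``lambda1 * sum_q ||C_{G_q}||_2 + lambda2 * ||C||_1``
  — gene-level selection plus within-gene feature selection;
* group ridge (squared-l1): ``lam * sum_q ||C_{G_q}||_1^2``
  — within-gene sparsity with ridge-like shrinkage across genes.

Because the groups do not overlap, every prox decomposes per group and
has an exact solution: block soft-thresholding for the group-l2 term,
elementwise soft-thresholding for l1, and a sorted active-set
computation for the squared-l1 term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CoefficientStack, GeneGroupIndex

__all__ = [
    "SparsityHyperparams",
    "prox_l1",
    "prox_group_l2",
    "prox_squared_l1_group",
    "penalty_value",
]


@dataclass
class SparsityHyperparams:
    """Penalty weights and the augmented-Lagrangian parameter.

    ``lambda1`` (group-l2 weight) and ``lambda2`` (l1 weight) drive the
    sparse group lasso; ``lam`` drives the group ridge.  ``rho`` is the
    ADMM augmented-Lagrangian parameter.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    lam: float = 0.0
    rho: float = 1.0

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lam) < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def prox_l1(z: np.ndarray, threshold: float) -> np.ndarray:
    """Elementwise soft-thresholding: ``sign(z) * max(|z| - t, 0)``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - threshold, 0.0)


def _group_indices(groups) -> list[np.ndarray]:
    if isinstance(groups, GeneGroupIndex):
        return [groups.stacked_slices[g] for g in groups.gene_ids]
    return [np.asarray(g, dtype=int) for g in groups]


def group_labels(groups, dim: int) -> np.ndarray:
    """Per-index group number for a non-overlapping covering grouping."""
    labels = np.full(dim, -1, dtype=int)
    for q, idx in enumerate(_group_indices(groups)):
        labels[idx] = q
    if (labels < 0).any():
        raise ValueError("groups do not cover all indices")
    return labels


def prox_group_l2(z: np.ndarray, groups, threshold: float,
                  labels: np.ndarray | None = None) -> np.ndarray:
    """Block soft-thresholding for the group-l2 penalty.

    Solves ``min_V 1/2 ||z - V||^2 + t * sum_q ||V_{G_q}||_2`` exactly:
    each group is scaled by ``max(0, 1 - t / ||z_g||)`` and groups with
    norm at or below the threshold are set exactly to zero.  ``groups``
    may be a :class:`GeneGroupIndex` or a list of index arrays;
    ``labels`` (from :func:`group_labels`) skips rebuilding the
    per-index group map in hot loops.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    z = np.asarray(z, dtype=float)
    if labels is None:
        labels = group_labels(groups, z.shape[0])
    norms = np.sqrt(np.bincount(labels, weights=z * z))
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > threshold, 1.0 - threshold /
                         np.where(norms > 0, norms, 1.0), 0.0)
    return scale[labels] * z


def _prox_squared_l1(zg: np.ndarray, c: float) -> np.ndarray:
    """Exact minimizer of ``1/2 ||z - v||^2 + c * ||v||_1^2`` for one group.

    At the optimum the nonzero entries satisfy
    ``v_i = sign(z_i) (|z_i| - t)`` with a common threshold
    ``t = 2c * ||v||_1``.  Sorting ``|z|`` descending, for an active set
    of the ``k`` largest entries the self-consistent threshold is
    ``t_k = 2c * S_k / (1 + 2ck)`` with ``S_k`` the partial sum; the
    correct ``k`` is the largest one with ``|z|_(k) > t_k``.
    """
    if c == 0:
        return zg.copy()
    a = np.abs(zg)
    order = np.argsort(-a)
    a_sorted = a[order]
    csum = np.cumsum(a_sorted)
    k = np.arange(1, len(zg) + 1)
    t_k = 2.0 * c * csum / (1.0 + 2.0 * c * k)
    active = a_sorted > t_k
    if not active.any():
        return np.zeros_like(zg)
    k_star = int(np.flatnonzero(active)[-1]) + 1
    t = t_k[k_star - 1]
    return np.sign(zg) * np.maximum(a - t, 0.0)


def prox_squared_l1_group(z: np.ndarray, groups, lam: float,
                          rho: float) -> np.ndarray:
    """Exact prox of the group ridge penalty.

    Solves ``min_V rho/2 ||z - V||^2 + lam * sum_q ||V_{G_q}||_1^2``
    group by group.  Signs of nonzero outputs match the signs of ``z``.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if rho <= 0:
        raise ValueError("rho must be positive")
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    c = lam / rho
    for idx in _group_indices(groups):
        out[idx] = _prox_squared_l1(z[idx], c)
    return out


def penalty_value(C, groups, hyperparams: SparsityHyperparams,
                  model_tag: str, labels: np.ndarray | None = None) -> float:
    """Value of the sparsity penalty at ``C``.

    ``sglasso``: ``lambda1 * sum_q ||C_g||_2 + lambda2 * ||C||_1``;
    ``sgridge``: ``lam * sum_q ||C_g||_1^2``.
    """
    values = C.values if isinstance(C, CoefficientStack) else np.asarray(C, float)
    if labels is None:
        labels = group_labels(groups, values.shape[0])
    if model_tag == "sglasso":
        g2 = np.sqrt(np.bincount(labels, weights=values * values)).sum()
        return float(hyperparams.lambda1 * g2
                     + hyperparams.lambda2 * np.abs(values).sum())
    if model_tag == "sgridge":
        g1 = np.bincount(labels, weights=np.abs(values))
        return float(hyperparams.lam * (g1 * g1).sum())
    raise ValueError(f"unknown model tag: {model_tag!r}")
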