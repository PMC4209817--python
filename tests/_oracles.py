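"""Independent numerical oracles for the proximal operators.

Each oracle takes a different mathematical route than the implementation
it checks:

* l1 prox — bounded scalar minimization of each coordinate's objective;
* group-l2 prox — Moreau decomposition: prox of a norm is the residual
  of the projection onto the dual-norm ball, and projecting onto an l2
  ball is elementary;
* squared-l1 group prox — positive/negative split ``v = a - b`` with
  ``a, b >= 0`` turns the objective into a smooth bound-constrained QP,
  solved by L-BFGS-B with an analytic gradient.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def oracle_prox_l1(z: np.ndarray, threshold: float) -> np.ndarray:
    out = np.empty_like(np.asarray(z, dtype=float))
    for i, zi in enumerate(np.ravel(z)):
        res = optimize.minimize_scalar(
            lambda v: 0.5 * (v - zi) ** 2 + threshold * abs(v),
            bounds=(-abs(zi) - 1.0, abs(zi) + 1.0), method="bounded",
            options={"xatol": 1e-12})
        out[i] = res.x
    return out


def oracle_prox_group_l2(z: np.ndarray, groups, threshold: float) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    for idx in groups:
        zg = z[idx]
        nrm = np.linalg.norm(zg)
        proj = zg if nrm <= threshold else zg * (threshold / nrm)
        out[idx] = zg - proj
    return out


def _solve_split_qp(zg: np.ndarray, lam: float, rho: float) -> np.ndarray:
    d = len(zg)

    def fg(x):
        a, b = x[:d], x[d:]
        v = a - b
        r = zg - v
        s = x.sum()
        f = 0.5 * rho * float(r @ r) + lam * s * s
        ga = -rho * r + 2.0 * lam * s
        gb = rho * r + 2.0 * lam * s
        return f, np.concatenate([ga, gb])

    x0 = np.concatenate([np.maximum(zg, 0.0), np.maximum(-zg, 0.0)])
    res = optimize.minimize(fg, x0, jac=True, method="L-BFGS-B",
                            bounds=[(0.0, None)] * (2 * d),
                            options={"ftol": 1e-16, "gtol": 1e-12,
                                     "maxiter": 5000})
    return res.x[:d] - res.x[d:]


def oracle_prox_squared_l1_group(z: np.ndarray, groups, lam: float,
                                 rho: float) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    for idx in groups:
        out[idx] = _solve_split_qp(z[idx], lam, rho)
    return out
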