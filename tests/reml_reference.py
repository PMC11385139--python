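"""Independent reference implementation of the restricted likelihood.

Used as the oracle for the AI-REML fits: the restricted log-likelihood is
written out directly from its definition (explicit V, slogdet, explicit
projection) and maximized with derivative-free Nelder-Mead from several
starts. Nothing here shares code with grmpart.reml.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def build_structures_uni(grms: list[np.ndarray], n: int) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float) for g in grms] + [np.eye(n)]


def build_structures_bi(grms, ind1, ind2):
    """Record-level derivative matrices for a stacked two-trait model.

    ind1/ind2: individual indices of the trait-1 and trait-2 records.
    Parameter order per term: var1, var2, cov12; terms = grms then residual.
    """
    n1, n2 = len(ind1), len(ind2)
    N = n1 + n2
    ds = []
    kernels = [np.asarray(g, dtype=float) for g in grms] + [None]
    for K in kernels:
        def k(a, b):
            return (1.0 if a == b else 0.0) if K is None else K[a, b]
        d11 = np.zeros((N, N))
        d22 = np.zeros((N, N))
        d12 = np.zeros((N, N))
        for i, a in enumerate(ind1):
            for j, b in enumerate(ind1):
                d11[i, j] = k(a, b)
        for i, a in enumerate(ind2):
            for j, b in enumerate(ind2):
                d22[n1 + i, n1 + j] = k(a, b)
        for i, a in enumerate(ind1):
            for j, b in enumerate(ind2):
                d12[i, n1 + j] = k(a, b)
                d12[n1 + j, i] = k(a, b)
        ds.extend([d11, d22, d12])
    return ds


def restricted_loglik(theta, y, X, structures) -> float:
    V = sum(t * D for t, D in zip(theta, structures))
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    s2, logdet_x = np.linalg.slogdet(XtViX)
    if s2 <= 0:
        return -np.inf
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    return float(-0.5 * (logdet_v + logdet_x + y @ P @ y))


def brute_maximize(y, X, structures, var_params, n_starts=4, seed=0):
    """Nelder-Mead maximization from several deterministic starts.

    var_params: indices of theta that must stay positive (variances).
    Returns (theta_hat, loglik).
    """
    rng = np.random.default_rng(seed)
    var_p = float(np.var(y, ddof=1))
    p = len(structures)

    def neg(theta):
        if any(theta[i] <= 0 for i in var_params):
            return np.inf
        ll = restricted_loglik(theta, y, X, structures)
        return np.inf if not np.isfinite(ll) else -ll

    best = None
    for s in range(n_starts):
        x0 = np.zeros(p)
        for i in range(p):
            if i in var_params:
                x0[i] = var_p / len(var_params) * (0.5 + rng.random())
            else:
                x0[i] = 0.05 * var_p * (rng.random() - 0.5)
        res = minimize(
            neg, x0, method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -best.fun
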