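"""Independent reference solvers and statistics used only as test oracles.

These deliberately avoid the package's own code paths: the L1-hinge problem
is solved as a linear program, the elastic-net hinge problem as a smooth
constrained program, AUC by explicit pair counting, and Fisher's exact p by
hypergeometric enumeration over all tables with the observed margins.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import LinearConstraint, linprog, minimize


def lasso_hinge_lp(X, y, lam):
    """Exact minimum of sum hinge + lam*||beta||_1 via LP.

    Variables: u, v >= 0 (beta = u - v), b0p, b0m >= 0 (beta0 = b0p - b0m),
    slacks xi >= 0 with xi_i >= 1 - y_i(x_i.(u-v) - beta0).
    Returns (beta, beta0, objective).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    # variable order: u(p), v(p), b0p, b0m, xi(n)
    c = np.concatenate([np.full(p, lam), np.full(p, lam), [0.0, 0.0], np.ones(n)])
    # constraint: y_i(X(u-v) - b0p + b0m) + xi_i >= 1
    A = np.zeros((n, 2 * p + 2 + n))
    A[:, :p] = y[:, None] * X
    A[:, p : 2 * p] = -y[:, None] * X
    A[:, 2 * p] = -y
    A[:, 2 * p + 1] = y
    A[:, 2 * p + 2 :] = np.eye(n)
    res = linprog(c, A_ub=-A, b_ub=-np.ones(n), bounds=[(0, None)] * (2 * p + 2 + n), method="highs")
    assert res.status == 0, res.message
    u = res.x[:p]
    v = res.x[p : 2 * p]
    beta = u - v
    beta0 = res.x[2 * p] - res.x[2 * p + 1]
    return beta, beta0, float(res.fun)


def elasticnet_hinge_qp(X, y, lam1, lam2):
    """Exact elastic-net hinge optimum via trust-constr on the constrained
    smooth formulation (slack variables make the objective differentiable)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    m = 2 * p + 1 + n  # u, v, beta0, xi

    def fun(z):
        u, v, xi = z[:p], z[p : 2 * p], z[2 * p + 1 :]
        beta = u - v
        return float(np.sum(xi) + lam1 * np.sum(u + v) + lam2 * np.sum(beta**2))

    def jac(z):
        u, v = z[:p], z[p : 2 * p]
        beta = u - v
        g = np.empty(m)
        g[:p] = lam1 + 2 * lam2 * beta
        g[p : 2 * p] = lam1 - 2 * lam2 * beta
        g[2 * p] = 0.0
        g[2 * p + 1 :] = 1.0
        return g

    # y_i((u-v).x_i - beta0) + xi_i >= 1 ; u,v,xi >= 0
    A = np.zeros((n, m))
    A[:, :p] = y[:, None] * X
    A[:, p : 2 * p] = -y[:, None] * X
    A[:, 2 * p] = -y
    A[:, 2 * p + 1 :] = np.eye(n)
    lc = LinearConstraint(A, lb=np.ones(n), ub=np.inf)
    bounds = [(0, None)] * p + [(0, None)] * p + [(None, None)] + [(0, None)] * n
    z0 = np.zeros(m)
    z0[2 * p + 1 :] = 1.0
    res = minimize(
        fun, z0, jac=jac, method="trust-constr", constraints=[lc], bounds=bounds,
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 3000},
    )
    beta = res.x[:p] - res.x[p : 2 * p]
    beta0 = float(res.x[2 * p])
    # report the true (non-slack) objective at the solution
    f = X @ beta - beta0
    obj = float(np.sum(np.maximum(0, 1 - y * f)) + lam1 * np.sum(np.abs(beta)) + lam2 * np.sum(beta**2))
    return beta, beta0, obj


def auc_pair_counting(scores, labels) -> float:
    """AUC as the fraction of (positive, negative) pairs where the positive
    outscores the negative; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    total = concordant = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                concordant += 1
            elif sp == sn:
                concordant += 0.5
    return concordant / total


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(x):
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = math.exp(logp(a))
    total = 0.0
    for x in range(lo, hi + 1):
        px = math.exp(logp(x))
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def holm_by_hand(p):
    """Step-down Holm adjustment, spelled out."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj
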