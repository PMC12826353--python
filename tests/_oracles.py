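"""Independent brute-force minimizers used as oracles in the solver tests.

Both penalized objectives are piecewise smooth: within a fixed sign pattern
of the penalized quantities (coefficients for the adaptive LASSO, edge
differences for the fused LASSO) the objective is smooth and convex.  The
global minimum is therefore the best smooth constrained minimum over all
sign patterns, which these helpers enumerate with scipy optimizers.  They
share no code with the package solvers.
"""

from itertools import product

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def _nll(X, y, coef):
    lp = X @ coef
    return float(np.sum(np.logaddexp(0.0, lp) - y * lp))


def _grad(X, y, coef):
    return X.T @ (expit(X @ coef) - y)


def brute_force_weighted_l1(X, y, pen, lam):
    """Global minimum of the weighted-L1 logistic objective by orthant search."""
    p = X.shape[1]
    shrink = [j for j in range(p) if pen[j] > 0]
    best = np.inf
    for signs in product((-1, 0, 1), repeat=len(shrink)):
        fixed_zero = [j for j, s in zip(shrink, signs) if s == 0]
        sign_of = {j: s for j, s in zip(shrink, signs) if s != 0}
        free = [j for j in range(p) if j not in fixed_zero]

        def obj(theta):
            coef = np.zeros(p)
            coef[free] = theta
            val = _nll(X, y, coef) + lam * sum(
                pen[j] * sign_of[j] * coef[j] for j in sign_of
            )
            g = _grad(X, y, coef)
            g_free = g[free] + lam * np.array(
                [pen[j] * sign_of.get(j, 0.0) for j in free]
            )
            return val, g_free

        bounds = [
            (0.0, None) if sign_of.get(j) == 1 else (None, 0.0) if sign_of.get(j) == -1 else (None, None)
            for j in free
        ]
        res = minimize(
            obj, np.zeros(len(free)), jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
        )
        coef = np.zeros(p)
        coef[free] = res.x
        val = _nll(X, y, coef) + lam * float(np.sum(pen * np.abs(coef)))
        best = min(best, val)
    return best


def brute_force_fused(X, y, edges, edge_w, lam1):
    """Global minimum of the graph-fused logistic objective by sign search.

    Reparametrizes each edge difference with an explicit sign constraint;
    for a 'fused' edge the two coefficients are tied through a shared free
    parameter (handled by an equality of columns).
    """
    p = X.shape[1]
    best = np.inf
    for signs in product((-1, 0, 1), repeat=len(edges)):
        # build a merge map for edges forced equal
        parent = list(range(p))

        def find(j):
            while parent[j] != j:
                parent[j] = parent[parent[j]]
                j = parent[j]
            return j

        for (u, v), s in zip(edges, signs):
            if s == 0:
                parent[find(u)] = find(v)
        reps = sorted({find(j) for j in range(p)})
        pos = {r: i for i, r in enumerate(reps)}
        M = np.zeros((p, len(reps)))
        for j in range(p):
            M[j, pos[find(j)]] = 1.0
        XM = X @ M

        cons = []
        for (u, v), s in zip(edges, signs):
            if s != 0:
                d = M[u] - M[v]
                cons.append({"type": "ineq", "fun": lambda th, d=d, s=s: s * (d @ th)})

        def obj(theta):
            coef = M @ theta
            val = _nll(X, y, coef)
            for (u, v), s, w in zip(edges, signs, edge_w):
                if s != 0:
                    val += lam1 * w * s * (coef[u] - coef[v])
            return val

        res = minimize(
            obj, np.zeros(len(reps)), method="SLSQP", constraints=cons,
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        coef = M @ res.x
        val = _nll(X, y, coef) + lam1 * sum(
            w * abs(coef[u] - coef[v]) for (u, v), w in zip(edges, edge_w)
        )
        best = min(best, val)
    return best
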