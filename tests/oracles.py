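"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the library
calls) they verify: the exact-test oracle enumerates hypergeometric tables
directly, the slope oracle is an explicit loop, the heterogeneity oracle
numerically maximises the Gaussian summary likelihood, and the 2x2
logistic oracle maximises the binomial likelihood on a grid-free scalar
parameterisation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def hypergeom_table_prob(a: int, row1: int, row2: int, col1: int) -> float:
    """P(top-left cell = a) for fixed margins, by log-factorials."""
    n = row1 + row2
    b = row1 - a
    c = col1 - a
    d = row2 - c
    if min(b, c, d) < 0:
        return 0.0
    lf = math.lgamma
    logp = (lf(row1 + 1) - lf(a + 1) - lf(b + 1)
            + lf(row2 + 1) - lf(c + 1) - lf(d + 1)
            - (lf(n + 1) - lf(col1 + 1) - lf(n - col1 + 1)))
    return math.exp(logp)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int,
                                 rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher P by full enumeration over all feasible tables.

    Sums the probabilities of every table (margins fixed) whose probability
    does not exceed the observed table's, within relative tolerance.
    """
    row1, row2, col1 = a + b, c + d, a + c
    p_obs = hypergeom_table_prob(a, row1, row2, col1)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        p = hypergeom_table_prob(x, row1, row2, col1)
        if p <= p_obs * (1.0 + rel_tol):
            total += p
    return min(total, 1.0)


def through_origin_slope_loop(xs, ys) -> float:
    """Least-squares slope through the origin by an explicit loop."""
    sxy = 0.0
    sxx = 0.0
    for x, y in zip(xs, ys):
        sxy += x * y
        sxx += x * x
    return sxy / sxx


def gaussian_common_effect_lrt(betas, ses) -> float:
    """2*(loglik_free - loglik_common) for Gaussian summaries, by numeric
    maximisation of the common-effect likelihood (no closed form used)."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)

    def negll(mu: float) -> float:
        return float((((betas - mu) / ses) ** 2).sum()) / 2.0

    span = abs(betas).max() + 10 * ses.max() + 1.0
    res = minimize_scalar(negll, bounds=(-span, span), method="bounded",
                          options={"xatol": 1e-12})
    # free model: each study at its own beta, residual term zero
    return 2.0 * (res.fun - 0.0)


def logistic_2x2_mle(a: int, b: int, c: int, d: int):
    """Maximum-likelihood log-OR and LRT chi2 for a saturated 2x2 logistic
    model (status ~ carrier), by direct binomial likelihood maximisation.

    Cells: a = case carriers, b = case non-carriers, c = control carriers,
    d = control non-carriers.
    """
    def ll(p_carrier: float, p_noncarrier: float) -> float:
        return (a * math.log(p_carrier) + c * math.log(1 - p_carrier)
                + b * math.log(p_noncarrier) + d * math.log(1 - p_noncarrier))

    # full model: independent case probabilities per carrier class (MLE is
    # the cell proportion; we confirm by scan rather than assume)
    def best_p(k: int, n: int) -> float:
        res = minimize_scalar(
            lambda q: -(k * math.log(q) + (n - k) * math.log(1 - q)),
            bounds=(1e-12, 1 - 1e-12), method="bounded",
            options={"xatol": 1e-14})
        return float(res.x)

    p1 = best_p(a, a + c)
    p0 = best_p(b, b + d)
    ll_full = ll(p1, p0)
    p_null = best_p(a + b, a + b + c + d)
    ll_null = ll(p_null, p_null)
    beta = math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))
    return beta, 2.0 * (ll_full - ll_null)


def welch_statistic(x, y):
    """Welch t statistic and degrees of freedom by direct arithmetic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df
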