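"""Independent desk oracles used by the test suite.

These deliberately re-derive results through different algorithms than the
package: a textbook tridiagonal natural-cubic-spline solver, a design-matrix
least-squares fit, and a sum-of-squares ANOVA decomposition.
"""

from __future__ import annotations

import numpy as np


def natural_cubic_spline_eval(x, y, xq):
    """Evaluate the natural cubic spline through (x, y) at points xq.

    Solves the tridiagonal system for the knot second derivatives M with
    natural boundary conditions (M[0] = M[-1] = 0) and evaluates the
    piecewise cubic; outside the knot range the end interval's cubic is
    continued.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xq = np.atleast_1d(np.asarray(xq, float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 knots")
    h = np.diff(x)
    m = np.zeros(n)
    if n > 2:
        # rows i=1..n-2: h[i-1] M[i-1] + 2(h[i-1]+h[i]) M[i] + h[i] M[i+1] = rhs
        a = np.zeros((n - 2, n - 2))
        rhs = np.zeros(n - 2)
        for i in range(1, n - 1):
            k = i - 1
            a[k, k] = 2.0 * (h[i - 1] + h[i])
            if k > 0:
                a[k, k - 1] = h[i - 1]
            if k < n - 3:
                a[k, k + 1] = h[i]
            rhs[k] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
        m[1:-1] = np.linalg.solve(a, rhs)
    out = np.empty_like(xq)
    idx = np.clip(np.searchsorted(x, xq) - 1, 0, n - 2)
    for k, (xv, i) in enumerate(zip(xq, idx)):
        hi = h[i]
        t0, t1 = x[i + 1] - xv, xv - x[i]
        out[k] = (
            m[i] * t0**3 / (6 * hi)
            + m[i + 1] * t1**3 / (6 * hi)
            + (y[i] / hi - m[i] * hi / 6) * t0
            + (y[i + 1] / hi - m[i + 1] * hi / 6) * t1
        )
    return out


def loglinear_ols_lstsq(t, y):
    """(s0, rate, r2) of ln(y) ~ t via numpy.linalg.lstsq on the design matrix."""
    t = np.asarray(t, float)
    logy = np.log(np.asarray(y, float))
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, logy, rcond=None)
    resid = logy - X @ beta
    sst = np.sum((logy - logy.mean()) ** 2)
    r2 = 1.0 if sst == 0 else 1.0 - np.sum(resid**2) / sst
    return float(np.exp(beta[0])), float(-beta[1]), float(r2)


def anova_f_oracle(groups):
    """One-way ANOVA F from the explicit sum-of-squares decomposition."""
    groups = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = sum(g.size for g in groups) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)
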