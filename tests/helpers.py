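"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit pair comparisons, full
enumeration, python loops) and shares no code with the library paths it
validates.
"""

import numpy as np


def ehh_bruteforce(H, carriers, core, j):
    """EHH at SNP j for the given carrier rows: compare every haplotype
    pair explicitly over the full segment between core and j (inclusive)."""
    lo, hi = (j, core) if j < core else (core, j)
    seg = H[np.asarray(carriers)][:, lo:hi + 1]
    n = seg.shape[0]
    same = 0
    for a in range(n):
        for b in range(a + 1, n):
            if np.array_equal(seg[a], seg[b]):
                same += 1
    total = n * (n - 1) // 2
    return same / total if total else 0.0


def artp_layer_bruteforce(P, grid):
    """ARTP single layer by triple loop, straight from its definition."""
    P = np.asarray(P, dtype=float)
    B1, L = P.shape
    W = np.empty((B1, len(grid)))
    for b in range(B1):
        sp = np.sort(P[b])
        for ki, k in enumerate(grid):
            W[b, ki] = np.prod(sp[:k])
    phat = np.empty_like(W)
    for b in range(B1):
        for ki in range(len(grid)):
            count = sum(1 for b2 in range(B1) if b2 != b and W[b2, ki] <= W[b, ki])
            phat[b, ki] = (1 + count) / B1
    minp = phat.min(axis=1)
    p = (1 + sum(1 for b in range(1, B1) if minp[b] <= minp[0])) / B1
    return p, minp


def score_test_p_single(g, X, y):
    """Efficient score test p for one SNP against a covariate-only
    logistic null, fitted here with statsmodels (independent route)."""
    import statsmodels.api as sm
    from scipy.stats import norm

    null = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    mu = null.fittedvalues
    w = mu * (1 - mu)
    U = g @ (y - mu)
    XtWX = (X * w[:, None]).T @ X
    XtWg = (X * w[:, None]).T @ g
    V = g @ (w * g) - XtWg @ np.linalg.solve(XtWX, XtWg)
    return 2 * norm.sf(abs(U) / np.sqrt(V))


def ols_perm_p_exhaustive(g, e):
    """Exhaustive permutation p for the OLS slope |t|, by enumeration."""
    from itertools import permutations
    from scipy import stats

    def abs_t(x, y):
        res = stats.linregress(x, y)
        return abs(res.slope / res.stderr)

    t_obs = abs_t(g, e)
    count = total = 0
    for perm in permutations(range(len(e))):
        t = abs_t(g, np.asarray(e)[list(perm)])
        total += 1
        if t >= t_obs - 1e-12:
            count += 1
    return count / total
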