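"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's eigenbasis/Woodbury shortcuts:
the mixed-model oracle evaluates the REML criterion on a dense grid of
variance ratios with explicit matrix inverses, and the OLS scan is a plain
per-marker least-squares Wald test.
"""

import numpy as np
from scipy import stats


def gls_grid_oracle(y, D, K, n_grid=10_000, log_bounds=(-5, 5)):
    """REML mixed-model fit by dense grid search over delta = s2_e/s2_g.

    Model: y = D b + u + e, u ~ N(0, s2_g K), e ~ N(0, s2_e I).
    Returns (beta_last, se_last, p_wald) for the last column of D.
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(D, dtype=float)
    n, q = D.shape

    def crit(log_delta):
        delta = 10.0 ** log_delta
        H = K + delta * np.eye(n)
        Hinv = np.linalg.inv(H)
        A = D.T @ Hinv @ D
        beta = np.linalg.solve(A, D.T @ Hinv @ y)
        r = y - D @ beta
        rss = float(r @ Hinv @ r)
        sign_h, logdet_H = np.linalg.slogdet(H)
        sign_a, logdet_A = np.linalg.slogdet(A)
        if sign_h <= 0 or sign_a <= 0 or rss <= 0:
            return np.inf
        return 0.5 * (logdet_H + logdet_A + (n - q) * np.log(rss))

    # dense grid, then two local refinements around the best cell
    lo, hi = log_bounds
    for size in (n_grid, 400, 400):
        grid = np.linspace(lo, hi, size)
        vals = [crit(ld) for ld in grid]
        i = int(np.argmin(vals))
        step = grid[1] - grid[0]
        lo, hi = grid[i] - step, grid[i] + step
    delta = 10.0 ** grid[i]
    H = K + delta * np.eye(n)
    Hinv = np.linalg.inv(H)
    A = D.T @ Hinv @ D
    beta = np.linalg.solve(A, D.T @ Hinv @ y)
    r = y - D @ beta
    s2 = float(r @ Hinv @ r) / (n - q)
    cov = s2 * np.linalg.inv(A)
    se = float(np.sqrt(cov[-1, -1]))
    b = float(beta[-1])
    p = float(stats.chi2.sf((b / se) ** 2, df=1))
    return b, se, p


def ols_scan_pvalues(y, X):
    """Naive per-marker OLS Wald p-values (intercept + marker)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    out = []
    for j in range(X.shape[1]):
        D = np.column_stack([np.ones(n), X[:, j]])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        r = y - D @ beta
        s2 = (r @ r) / (n - 2)
        cov = s2 * np.linalg.inv(D.T @ D)
        stat = beta[1] ** 2 / cov[1, 1]
        out.append(stats.chi2.sf(stat, df=1))
    return np.array(out)
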