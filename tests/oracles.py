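"""Independent brute-force reference implementations used only by tests.

Each oracle follows the plainest possible route (explicit loops, closed
forms) and shares no code with the package paths it checks.
"""

import numpy as np
from scipy import stats


def brute_force_grm(dosages):
    """Centered GRM by an explicit double loop over sample pairs.

    Missing cells (< 0) are replaced by the site mean first.
    """
    X = np.asarray(dosages, float).copy()
    n, p = X.shape
    for j in range(p):
        col = X[:, j]
        m = col[col >= 0].mean()
        col[col < 0] = m
        X[:, j] = col - col.mean()
    K = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            acc = 0.0
            for j in range(p):
                acc += X[i, j] * X[k, j]
            K[i, k] = acc / p
    return K


def brute_force_signal_clusters(records, p_threshold, window):
    """O(n^2) greedy peak clustering on a list of (chrom, pos, p) tuples.

    Returns a list of (index_record, member_records) with members sorted by
    position, signals sorted by index (chrom, pos).
    """
    half = window // 2
    pool = [r for r in records if r[2] < p_threshold]
    out = []
    while pool:
        idx = min(pool, key=lambda r: (r[2], r[0], r[1]))
        members = [r for r in pool if r[0] == idx[0] and abs(r[1] - idx[1]) <= half]
        for m in members:
            pool.remove(m)
        out.append((idx, sorted(members, key=lambda r: r[1])))
    out.sort(key=lambda s: (s[0][0], s[0][1]))
    return out


def ols_score_test(y, x, covariates=None):
    """Closed-form 1-df score test for a linear regression slope.

    Residualizes y and x on the covariates (plus intercept), uses the
    restricted residual variance estimate, and refers the statistic to
    chi-square(1).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    W = np.ones((n, 1))
    if covariates is not None:
        W = np.column_stack([W, covariates])
    H = W @ np.linalg.inv(W.T @ W) @ W.T
    ry = y - H @ y
    rx = x - H @ x
    sigma2 = ry @ ry / (n - W.shape[1])
    stat = (rx @ ry) ** 2 / (sigma2 * (rx @ rx))
    return stat, stats.chi2.sf(stat, df=1)
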