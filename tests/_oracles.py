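"""Independent brute-force oracles used only by the tests.

These deliberately materialize full matrices and stay naive, so they cannot
share a bug with the blocked/trace implementations they check.
"""

import numpy as np

LOG2PI = np.log(2.0 * np.pi)


def brute_observation_variances(Z, Sigma):
    """diag(Z Sigma Z') via the explicit n x n product."""
    full = Z @ Sigma @ Z.T
    return np.diag(full).copy()


def brute_mean_variance(Z, Sigma):
    """Tr(Z Sigma Z') / n via the explicit n x n product."""
    return float(np.trace(Z @ Sigma @ Z.T)) / Z.shape[0]


def theta_to_lambda(theta, k):
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = np.asarray(theta, dtype=float)
    return L


def dense_criterion(theta, y, X, Z, groups, method="REML"):
    """-2 profiled (restricted) log-likelihood via the explicit n x n
    marginal covariance V0 = I + Z_full G Z_full'."""
    k = Z.shape[1]
    L = theta_to_lambda(theta, k)
    G = L @ L.T
    n, p = X.shape
    V0 = np.eye(n)
    for g in np.unique(groups):
        idx = np.where(np.asarray(groups) == g)[0]
        Zg = Z[idx]
        V0[np.ix_(idx, idx)] += Zg @ G @ Zg.T
    Vi = np.linalg.inv(V0)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    rss = r @ Vi @ r
    sld = np.linalg.slogdet(V0)[1]
    if method == "ML":
        s2 = rss / n
        return n * (LOG2PI + np.log(s2)) + sld + n
    s2 = rss / (n - p)
    return (
        (n - p) * (LOG2PI + np.log(s2))
        + sld
        + np.linalg.slogdet(A)[1]
        + (n - p)
    )
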