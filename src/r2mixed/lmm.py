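"""Self-contained REML/ML fitting of Gaussian linear mixed models.

Fits the single-grouping-factor LMM

    y_ij = x_ij' beta + z_ij' a_j + eps_ij,
    a_j ~ N(0, Sigma),   eps_ij ~ N(0, sigma2_eps),

covering random intercepts (k = 1), correlated random intercept + slope
(k = 2) and slope-only (no random intercept) specifications.

The covariance is parameterized through the lower-triangular relative
covariance factor Lambda with Sigma = sigma2_eps * Lambda Lambda', so the
estimate is positive semi-definite by construction and beta and sigma2_eps
profile out of the likelihood in closed form.  The criterion is evaluated
group-blockwise via the Woodbury identity: per group only the k x k matrix
M_j = I + Lambda' Z_j' Z_j Lambda is factorized, so no n x n matrix is ever
formed.  The profiled -2 log-likelihood minimized over theta (the k(k+1)/2
free entries of Lambda) is, with V0 the relative covariance I + Z G Z':

    ML:   n log(2 pi s2) + log|V0| + n,              s2 = r' V0^-1 r / n
    REML: (n-p) log(2 pi s2) + log|V0| + log|X' V0^-1 X| + (n-p),
                                                     s2 = r' V0^-1 r / (n-p)

with r the residual at the generalized-least-squares beta-hat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .components import ModelComponents, RandomEffectTerm, build_random_design
from .exceptions import ConvergenceError, DegenerateModelError, InputError

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)

#: Relative-criterion convergence tolerance and iteration cap.
FTOL = 1e-8
MAX_ITER = 500


@dataclass
class FitResult:
    """A fitted Gaussian LMM ready for variance partitioning.

    ``components`` carries the estimated fixed effects, the random-effect
    term with its estimated ``Sigma``, and the residual variance.
    ``loglik`` is the (restricted) log-likelihood at the optimum.
    """

    components: ModelComponents
    loglik: float
    method: str
    converged: bool
    n_groups: int
    iterations: int
    boundary: bool = False

    @property
    def beta(self) -> np.ndarray:
        return self.components.beta

    @property
    def Sigma(self) -> np.ndarray:
        return self.components.terms[0].Sigma

    @property
    def sigma2_eps(self) -> float:
        return self.components.sigma2_e

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "Sigma": self.Sigma.tolist(),
            "sigma2_eps": self.sigma2_eps,
            "loglik": self.loglik,
            "method": self.method,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_groups": self.n_groups,
            "iterations": self.iterations,
        }


def _theta_to_lambda(theta: np.ndarray, k: int) -> np.ndarray:
    """Unpack theta into the lower-triangular factor Lambda (row-major)."""
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = theta
    return L


def _lambda_to_theta(L: np.ndarray) -> np.ndarray:
    return L[np.tril_indices(L.shape[0])]


class _BlockData:
    """Per-group views of (y, X, Z) for blockwise likelihood evaluation."""

    def __init__(self, y, X, Z, groups):
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        self.Z = Z[order]
        g = np.asarray(groups)[order]
        _, starts = np.unique(g, return_index=True)
        self.bounds = np.append(np.sort(starts), len(g))
        self.n_groups = len(self.bounds) - 1
        self.n, self.p = self.X.shape
        self.k = self.Z.shape[1]

    def blocks(self):
        for j in range(self.n_groups):
            s, e = self.bounds[j], self.bounds[j + 1]
            yield self.y[s:e], self.X[s:e], self.Z[s:e]


def _profiled_pieces(theta: np.ndarray, data: _BlockData):
    """Accumulate logdet(V0), X'V0^-1 X, X'V0^-1 y, y'V0^-1 y blockwise."""
    k, p = data.k, data.p
    L = _theta_to_lambda(theta, k)
    logdet = 0.0
    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    ytwy = 0.0
    for y_j, X_j, Z_j in data.blocks():
        U = Z_j @ L  # n_j x k
        M = np.eye(k) + U.T @ U
        cF = np.linalg.cholesky(M)
        logdet += 2.0 * np.log(np.diag(cF)).sum()
        # V0_j^-1 = I - U M^-1 U'
        Uty = U.T @ y_j
        UtX = U.T @ X_j
        sy = np.linalg.solve(M, Uty)
        sX = np.linalg.solve(M, UtX)
        xtwx += X_j.T @ X_j - UtX.T @ sX
        xtwy += X_j.T @ y_j - UtX.T @ sy
        ytwy += y_j @ y_j - Uty @ sy
    return logdet, xtwx, xtwy, ytwy


def profiled_criterion(theta, data, method: str = "REML") -> float:
    """-2 x profiled (restricted) log-likelihood at theta.

    ``data`` is a :class:`_BlockData` or a ``(y, X, Z, groups)`` tuple.
    At theta = 0 the criterion reduces to the ordinary least-squares
    deviance (no random effects).
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if not np.isfinite(theta).all():
        raise InputError("theta contains non-finite entries")
    if not isinstance(data, _BlockData):
        data = _BlockData(*data)
    logdet, xtwx, xtwy, ytwy = _profiled_pieces(theta, data)
    n, p = data.n, data.p
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        raise InputError("fixed-effects design is singular")
    beta = np.linalg.solve(xtwx, xtwy)
    rss = ytwy - xtwy @ beta
    rss = max(rss, np.finfo(float).tiny)
    if method == "ML":
        s2 = rss / n
        return n * (LOG2PI + np.log(s2)) + logdet + n
    if method == "REML":
        df = n - p
        s2 = rss / df
        return df * (LOG2PI + np.log(s2)) + logdet + logdet_xtwx + df
    raise InputError(f"unknown method '{method}'")


def _solve_beta_s2(theta, data, method):
    logdet, xtwx, xtwy, ytwy = _profiled_pieces(theta, data)
    beta = np.linalg.solve(xtwx, xtwy)
    rss = max(ytwy - xtwy @ beta, 0.0)
    df = data.n if method == "ML" else data.n - data.p
    return beta, rss / df


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed_columns: list[str] | None = None,
    random_intercept: bool = True,
    random_slopes: list[str] | None = None,
    grouping_column: str = "group",
    fixed_intercept: bool = True,
    method: str = "REML",
) -> FitResult:
    """Fit a Gaussian LMM with one random-effect grouping factor.

    Parameters
    ----------
    data : pandas.DataFrame
        Table with the response, fixed covariates, slope covariates and the
        grouping factor.  Rows with missing values in used columns are
        dropped.
    response : str
        Response column (must be numeric).
    fixed_columns : list of str
        Fixed-covariate columns; an intercept column is prepended when
        ``fixed_intercept`` is true.
    random_intercept, random_slopes, grouping_column
        The random-effect term specification, as in
        :func:`~r2mixed.components.build_random_design`.
    method : {"REML", "ML"}
        REML is the default since the variance components are the
        quantities of interest; use ML to compare nested fixed structures.
    """
    if method not in ("REML", "ML"):
        raise InputError(f"unknown method '{method}'")
    fixed_columns = list(fixed_columns or [])
    random_slopes = list(random_slopes or [])

    used = [response, *fixed_columns, *random_slopes, grouping_column]
    from .components import drop_missing

    data = drop_missing(data, list(dict.fromkeys(used)))
    n = len(data)
    if n < 2:
        raise InputError("need at least 2 observations")

    y = data[response].to_numpy(dtype=float)
    term = build_random_design(
        data,
        intercept=random_intercept,
        slope_columns=random_slopes,
        grouping_column=grouping_column,
    )
    groups = term.grouping
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise InputError(f"need at least 2 groups, got {n_groups}")

    xcols = []
    if fixed_intercept:
        xcols.append(np.ones(n))
    for c in fixed_columns:
        xcols.append(data[c].to_numpy(dtype=float))
    X = np.column_stack(xcols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("fixed-effects design matrix is rank deficient")
    if np.var(y) == 0:
        raise DegenerateModelError("response is constant; no variance to model")
    ols_rss = float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
    if ols_rss <= 1e-12 * float(y @ y):
        raise DegenerateModelError(
            "response is an exact linear function of the fixed effects; "
            "no residual variance to model"
        )

    block = _BlockData(y, X, term.Z, groups)
    k = block.k

    theta0 = _lambda_to_theta(0.5 * np.eye(k))
    diag_idx = np.cumsum(np.arange(1, k + 1)) - 1
    bounds = [
        (0.0, None) if i in diag_idx else (None, None)
        for i in range(k * (k + 1) // 2)
    ]

    res = optimize.minimize(
        profiled_criterion,
        theta0,
        args=(block, method),
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": FTOL, "maxiter": MAX_ITER, "maxfun": 20 * MAX_ITER},
    )
    theta_hat = res.x
    converged = bool(res.success)
    if not converged and not np.isfinite(res.fun):
        raise ConvergenceError(
            f"optimizer failed: {res.message}", best_state={"theta": theta_hat}
        )

    L = _theta_to_lambda(theta_hat, k)
    beta, s2 = _solve_beta_s2(theta_hat, block, method)
    Sigma = s2 * (L @ L.T)
    boundary = bool(np.any(np.abs(np.diag(L)) < 1e-6))
    if boundary:
        logger.info("variance estimate at boundary (a diagonal of Lambda is ~0)")

    # rebuild term on the sorted-row order used internally, so Z and X in the
    # returned components are row-aligned
    term_out = RandomEffectTerm(
        label=term.label, Z=block.Z, Sigma=Sigma, grouping=None
    )
    components = ModelComponents(
        X=block.X,
        beta=beta,
        terms=[term_out],
        sigma2_e=float(s2),
        family_link="gaussian-identity",
    )
    return FitResult(
        components=components,
        loglik=-0.5 * float(res.fun),
        method=method,
        converged=converged,
        n_groups=n_groups,
        iterations=int(res.nit),
        boundary=boundary,
    )
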