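"""Variance partitioning and R² for mixed models with random slopes.

In a random-intercepts model every observation shares the same random-effect
variance, so the variance explained by a grouping factor is just the
intercept variance.  With random slopes the random-effect variance depends on
the covariate value: for design row ``z_i`` (e.g. ``[1, x_i]``) and effect
covariance ``Sigma`` it is the quadratic form ``z_i' Sigma z_i`` — the i-th
diagonal entry of ``Z Sigma Z'``.  The random part of the model is then a
mixture of n zero-mean normals, and since a zero-mean mixture's variance is
the mean of the component variances, the term's single variance component is

    sigma2_bar = Tr(Z Sigma Z') / n.

This reduces to the intercept variance when ``Z`` is a column of ones, and
applies equally to slope-only (no-intercept) terms.  Marginal R² is the fixed
-effect variance as a share of the total (fixed + random + additive
dispersion + distribution-specific); conditional R² adds the random-effect
variances to the numerator.  The same observation-level quadratic form gives
an intraclass correlation conditioned on a covariate value.
"""

from __future__ import annotations

import math

import numpy as np

from .components import (
    ModelComponents,
    R2Result,
    RandomEffectTerm,
    VariancePartition,
)
from .exceptions import DegenerateModelError, InputError, R2MixedError

#: Diagonal entries of Z Sigma Z' more negative than this are an error;
#: values in (-CLIP_TOL, 0) are floating-point noise from a PSD-boundary
#: Sigma and are clipped to zero.
CLIP_TOL = 1e-10


def _require_sigma(term: RandomEffectTerm) -> np.ndarray:
    if term.Sigma is None:
        raise R2MixedError(
            f"term '{term.label}' has no Sigma set; fit the model or supply one"
        )
    if term.Sigma.shape[0] != term.k:
        raise InputError(
            f"term '{term.label}': Sigma dimension {term.Sigma.shape[0]} "
            f"does not match k={term.k}"
        )
    return term.Sigma


def observation_variances(term: RandomEffectTerm) -> np.ndarray:
    """Observation-level random-effect variances diag(Z Sigma Z').

    Element i is the quadratic form ``z_i' Sigma z_i`` — the variance
    contributed by the term's random effects at observation i's covariate
    values.  Computed row-wise without materializing the n x n matrix.
    """
    Sigma = _require_sigma(term)
    v = np.einsum("ij,jk,ik->i", term.Z, Sigma, term.Z)
    low = v.min(initial=0.0)
    if low < -CLIP_TOL:
        raise R2MixedError(
            f"negative observation variance {low:g}: Sigma is not PSD enough"
        )
    return np.clip(v, 0.0, None)


def mean_random_effect_variance(term: RandomEffectTerm) -> float:
    """Mean random-effect variance Tr(Z Sigma Z') / n of one term.

    Evaluated as ``Tr(Sigma @ Z'Z) / n`` (trace is invariant under cyclic
    permutation), which avoids forming the n x n matrix and equals the mean
    of :func:`observation_variances` exactly.
    """
    Sigma = _require_sigma(term)
    n = term.n_obs
    if n == 0:
        raise InputError("term has zero observations")
    # dividing Z'Z by n before the trace keeps the random-intercepts
    # reduction (Z = ones => value = Sigma[0, 0]) exact in floating point
    ztz = (term.Z.T @ term.Z) / n
    val = float(np.trace(Sigma @ ztz))
    if val < -CLIP_TOL:
        raise R2MixedError(f"negative mean random-effect variance {val:g}")
    return max(val, 0.0)


def fixed_effects_variance(X: np.ndarray, beta: np.ndarray) -> float:
    """Variance of the fixed-effect linear predictor X @ beta.

    Uses the sample variance (denominator n - 1); the distinction from the
    population variance is O(1/n) and immaterial for model-level R².
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float).ravel()
    if X.shape[0] < 2:
        raise InputError("need at least 2 observations to compute a variance")
    if X.shape[1] != beta.shape[0]:
        raise InputError("X and beta dimensions do not agree")
    eta = X @ beta
    return float(np.var(eta, ddof=1))


def estimate_beta0(X: np.ndarray, beta: np.ndarray) -> float:
    """Estimate the intercept-at-the-mean as mean(X @ beta).

    The distribution-specific variance of a Poisson log-link model depends on
    the baseline rate exp(beta0).  Rather than refitting the model with
    centred covariates, beta0 is taken as the mean of the linear predictor;
    with centred covariates and an intercept column this equals the fitted
    intercept exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float).ravel()
    if X.size == 0:
        raise InputError("X is empty")
    if X.shape[1] != beta.shape[0]:
        raise InputError("X and beta dimensions do not agree")
    return float(np.mean(X @ beta))


def distribution_specific_variance(family_link: str, beta0: float = 0.0) -> float:
    """Link-scale variance implied by the response distribution.

    gaussian-identity -> 0; binomial-logit -> pi^2/3; binomial-probit -> 1;
    poisson-log -> ln(1 + 1/exp(beta0)) (lognormal-Poisson approximation,
    decreasing in the baseline rate); poisson-sqrt -> 0.25.
    """
    if family_link == "gaussian-identity":
        return 0.0
    if family_link == "binomial-logit":
        return math.pi**2 / 3.0
    if family_link == "binomial-probit":
        return 1.0
    if family_link == "poisson-log":
        if not np.isfinite(beta0):
            raise InputError("beta0 must be finite for a Poisson log-link model")
        return math.log1p(math.exp(-beta0))
    if family_link == "poisson-sqrt":
        return 0.25
    raise InputError(f"unknown family_link '{family_link}'")


def assemble_partition(components: ModelComponents) -> VariancePartition:
    """Compute all variance components of a model.

    Fixed-effect variance from the linear predictor; one mean random-effect
    variance per term (independent terms, so they add); additive dispersion
    passed through; distribution-specific variance from the family and the
    mean linear predictor.
    """
    sigma2_f = fixed_effects_variance(components.X, components.beta)
    sigma2_terms = [mean_random_effect_variance(t) for t in components.terms]
    beta0 = estimate_beta0(components.X, components.beta)
    sigma2_d = distribution_specific_variance(components.family_link, beta0)
    part = VariancePartition(
        sigma2_f=sigma2_f,
        sigma2_terms=sigma2_terms,
        sigma2_e=float(components.sigma2_e),
        sigma2_d=sigma2_d,
    )
    if part.total <= 0:
        raise DegenerateModelError("total variance is zero; nothing to partition")
    return part


def r2_marginal(partition: VariancePartition) -> float:
    """Share of total variance explained by the fixed effects alone."""
    total = partition.total
    if total <= 0:
        raise DegenerateModelError("total variance is zero")
    return partition.sigma2_f / total


def r2_conditional(partition: VariancePartition) -> float:
    """Share of total variance explained by fixed and random effects jointly."""
    total = partition.total
    if total <= 0:
        raise DegenerateModelError("total variance is zero")
    return (partition.sigma2_f + sum(partition.sigma2_terms)) / total


def r2_glmm(components: ModelComponents) -> R2Result:
    """Convenience wrapper: partition the variance and compute both R²."""
    part = assemble_partition(components)
    return R2Result(
        marginal=r2_marginal(part), conditional=r2_conditional(part), partition=part
    )


def icc_conditional(
    term: RandomEffectTerm,
    sigma2_e: float,
    sigma2_d: float = 0.0,
    covariate_values=(0.0,),
) -> np.ndarray:
    """Intraclass correlation conditioned on values of the slope covariate.

    For each value v the between-group variance at v is the quadratic form
    ``[1, v]' Sigma [1, v]`` (or ``[v]' Sigma [v]`` for a no-intercept term),
    and the ICC is that variance over itself plus residual-scale variance.
    E.g. repeatability of a phenotype conditioned on a range of ages.
    """
    Sigma = _require_sigma(term)
    has_intercept = np.allclose(term.Z[:, 0], 1.0)
    n_slopes = term.k - (1 if has_intercept else 0)
    if n_slopes > 1 or (n_slopes == 0 and not has_intercept):
        raise InputError(
            "icc_conditional needs exactly one slope covariate to condition on "
            "(or an intercept-only term, where the ICC is constant)"
        )
    values = np.asarray(covariate_values, dtype=float).ravel()
    if not np.isfinite(values).all():
        raise InputError("covariate values must be finite")
    out = np.empty_like(values)
    for i, v in enumerate(values):
        if n_slopes == 0:
            row = np.array([1.0])
        elif has_intercept:
            row = np.array([1.0, v])
        else:
            row = np.array([v])
        var_alpha = float(row @ Sigma @ row)
        var_alpha = max(var_alpha, 0.0)
        denom = var_alpha + sigma2_e + sigma2_d
        if denom <= 0:
            raise DegenerateModelError(
                f"zero total variance at covariate value {v}: ICC undefined"
            )
        out[i] = var_alpha / denom
    return out
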