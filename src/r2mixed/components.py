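"""Domain types for variance partitioning in mixed models.

The central objects are :class:`RandomEffectTerm` (a random-effect design
matrix ``Z`` over the covariates, paired with the covariance matrix ``Sigma``
of the effects) and :class:`ModelComponents` (everything needed to partition
the variance of a fitted mixed model: fixed design and estimates, the
random-effect terms, the residual variance and the response family/link).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CovarianceError, InputError

logger = logging.getLogger(__name__)

#: Supported response family / link combinations.
FAMILIES = (
    "gaussian-identity",
    "poisson-log",
    "poisson-sqrt",
    "binomial-logit",
    "binomial-probit",
)


def validate_covariance(Sigma, tol: float = 1e-8) -> np.ndarray:
    """Validate and symmetrize a random-effect covariance matrix.

    Parameters
    ----------
    Sigma : array-like, shape (k, k)
        Candidate covariance matrix.
    tol : float
        Relative tolerance for both the asymmetry check and the
        positive-semi-definiteness check (eigenvalues may dip below zero by
        at most ``tol`` times the spectral norm).

    Returns
    -------
    numpy.ndarray
        The symmetrized matrix ``(Sigma + Sigma.T) / 2``.

    Raises
    ------
    CovarianceError
        If the matrix is not square, is asymmetric beyond ``tol`` or has an
        eigenvalue below ``-tol * spectral_norm``.
    """
    S = np.asarray(Sigma, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise CovarianceError(f"covariance matrix must be square, got shape {S.shape}")
    scale = max(np.abs(S).max(), 1.0)
    asym = np.abs(S - S.T).max()
    if asym > tol * scale:
        raise CovarianceError(
            f"covariance matrix asymmetric: max |S - S'| = {asym:g} exceeds tolerance"
        )
    S = (S + S.T) / 2.0
    eigvals = np.linalg.eigvalsh(S)
    spectral = max(np.abs(eigvals).max(), np.finfo(float).tiny)
    if eigvals[0] < -tol * spectral:
        raise CovarianceError(
            f"covariance matrix is not positive semi-definite: "
            f"eigenvalue {eigvals[0]:g} < {-tol * spectral:g}"
        )
    return S


@dataclass
class RandomEffectTerm:
    """One random-effect block of a mixed model.

    Attributes
    ----------
    label : str
        Name of the term (usually the grouping factor).
    Z : numpy.ndarray, shape (n, k)
        Term-level random-effect design over the covariates.  When the term
        includes a random intercept the first column is all ones; remaining
        columns hold the slope covariates.  This is the n x k formulation:
        groups share ``Sigma`` and have mean zero, so the observation-level
        variance depends only on the covariate values, not on group identity.
    Sigma : numpy.ndarray or None, shape (k, k)
        Covariance matrix of the k random effects.  ``None`` until estimated
        or supplied.
    grouping : numpy.ndarray or None, shape (n,)
        Group label per observation.  Used by the fitter; the variance
        computations do not need it.
    """

    label: str
    Z: np.ndarray
    Sigma: np.ndarray | None = None
    grouping: np.ndarray | None = None

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise InputError(f"Z must be 2-dimensional, got ndim={self.Z.ndim}")
        if self.Z.shape[1] < 1:
            raise InputError("Z must have at least one column (k >= 1)")
        if not np.isfinite(self.Z).all():
            raise InputError("Z contains missing or non-finite entries")
        if self.Sigma is not None:
            self.Sigma = validate_covariance(self.Sigma)
            if self.Sigma.shape[0] != self.k:
                raise InputError(
                    f"Sigma is {self.Sigma.shape[0]}x{self.Sigma.shape[0]} but Z has "
                    f"k={self.k} columns"
                )
            if (np.diag(self.Sigma) < 0).any():
                raise CovarianceError("Sigma has a negative diagonal entry")
        if self.grouping is not None:
            self.grouping = np.asarray(self.grouping)
            if self.grouping.shape[0] != self.n_obs:
                raise InputError("grouping length does not match number of rows of Z")

    @property
    def n_obs(self) -> int:
        return self.Z.shape[0]

    @property
    def k(self) -> int:
        return self.Z.shape[1]


@dataclass
class ModelComponents:
    """Everything needed to partition the variance of a (G)LMM.

    ``X @ beta`` is the fixed-effect linear predictor on the link scale;
    ``terms`` are the random-effect blocks; ``sigma2_e`` is the additive
    dispersion (for a Gaussian model, the residual variance); ``family_link``
    selects the distribution-specific variance.
    """

    X: np.ndarray
    beta: np.ndarray
    terms: list[RandomEffectTerm] = field(default_factory=list)
    sigma2_e: float = 0.0
    family_link: str = "gaussian-identity"

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.X.shape[1] != self.beta.shape[0]:
            raise InputError(
                f"X has {self.X.shape[1]} columns but beta has length {self.beta.shape[0]}"
            )
        if not np.isfinite(self.X).all() or not np.isfinite(self.beta).all():
            raise InputError("X or beta contains non-finite entries")
        n = self.X.shape[0]
        for t in self.terms:
            if t.n_obs != n:
                raise InputError(
                    f"term '{t.label}' has {t.n_obs} rows but X has {n} rows"
                )
        if self.sigma2_e < 0:
            raise InputError(f"sigma2_e must be non-negative, got {self.sigma2_e}")
        if self.family_link not in FAMILIES:
            raise InputError(
                f"unknown family_link '{self.family_link}'; expected one of {FAMILIES}"
            )

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


@dataclass
class VariancePartition:
    """Named variance components of a mixed model on the link scale.

    ``sigma2_f``: variance of the fixed-effect linear predictor.
    ``sigma2_terms``: mean random-effect variance of each term.
    ``sigma2_e``: additive dispersion / residual variance.
    ``sigma2_d``: distribution-specific variance.
    """

    sigma2_f: float
    sigma2_terms: list[float]
    sigma2_e: float
    sigma2_d: float

    @property
    def total(self) -> float:
        return self.sigma2_f + sum(self.sigma2_terms) + self.sigma2_e + self.sigma2_d

    def to_dict(self) -> dict:
        return {
            "sigma2_f": self.sigma2_f,
            "sigma2_terms": list(self.sigma2_terms),
            "sigma2_e": self.sigma2_e,
            "sigma2_d": self.sigma2_d,
        }


@dataclass
class R2Result:
    """Marginal and conditional R-squared with the component breakdown."""

    marginal: float
    conditional: float
    partition: VariancePartition

    def to_dict(self) -> dict:
        d = self.partition.to_dict()
        d["r2_marginal"] = self.marginal
        d["r2_conditional"] = self.conditional
        return d


def drop_missing(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Drop rows with missing values in any of ``columns``, logging the count."""
    missing_cols = [c for c in columns if c not in data.columns]
    if missing_cols:
        raise InputError(f"columns not found in data table: {missing_cols}")
    mask = data[columns].notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("dropping %d rows with missing values in %s", n_drop, columns)
    return data.loc[mask]


def build_random_design(
    data: pd.DataFrame,
    intercept: bool = True,
    slope_columns: list[str] | None = None,
    grouping_column: str | None = None,
    label: str | None = None,
) -> RandomEffectTerm:
    """Build a random-effect design matrix from a data table.

    Columns of ``Z`` are ordered ``[intercept?, slopes in given order]``;
    ``Sigma`` is left unset, to be filled by the fitter or by the user.
    Rows with missing values in any used column are dropped.
    """
    slope_columns = list(slope_columns or [])
    if not intercept and not slope_columns:
        raise InputError("zero random effects requested: need an intercept or slopes")
    used = list(slope_columns)
    if grouping_column is not None:
        used.append(grouping_column)
    data = drop_missing(data, used) if used else data
    n = len(data)
    cols = []
    if intercept:
        cols.append(np.ones(n))
    for c in slope_columns:
        col = data[c]
        if not pd.api.types.is_numeric_dtype(col):
            raise InputError(f"slope column '{c}' is not numeric")
        cols.append(col.to_numpy(dtype=float))
    Z = np.column_stack(cols)
    grouping = (
        data[grouping_column].to_numpy() if grouping_column is not None else None
    )
    if label is None:
        label = grouping_column or "random"
    return RandomEffectTerm(label=label, Z=Z, grouping=grouping)
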