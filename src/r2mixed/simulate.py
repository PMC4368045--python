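"""Seeded simulation of random-slopes mixed-model data.

Generates datasets from the model

    y_ij = (beta0 + a0_j) + (beta1 + a1_j) x_ij + eps_ij,
    (a0_j, a1_j) ~ MVN(0, Sigma),  eps_ij ~ N(0, sigma2_eps)

for a Gaussian response, or the log-link Poisson analogue
``y ~ Poisson(exp(eta))`` with sigma2_eps = 0 and an optional observation
-level normal intercept acting as additive overdispersion.  Alongside each
dataset the analytic "true" variance partition at the generating parameters
is available, so estimator-recovery tests have an exact target.

Designs can be balanced (equal group sizes, one shared covariate
distribution) or unbalanced (one dominant group supplying most of the
observations, optionally with its own covariate range) — the scenario in
which a random-intercepts fit biases the global slope toward the dominant
group while a random-slopes fit does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import VariancePartition, validate_covariance
from .exceptions import InputError
from .partition import distribution_specific_variance

#: Default shared covariate range: x ~ Uniform(0, 1) in every group.
DEFAULT_RANGE = (0.0, 1.0)


@dataclass
class SimulationSpec:
    """True parameters and design layout for one simulated dataset.

    ``group_sizes`` may be an int (balanced: every one of ``n_groups``
    groups gets that many observations) or an explicit per-group list.
    ``group_ranges`` optionally gives a (lo, hi) uniform covariate range per
    group; by default all groups share Uniform(0, 1).  ``sigma2_obs`` adds a
    per-observation normal intercept (additive overdispersion) for the
    Poisson family and is reported as sigma2_e in the true partition.
    """

    n_groups: int = 100
    group_sizes: int | list[int] = 10
    beta: tuple[float, float] = (0.5, 1.0)
    Sigma: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.25], [0.25, 0.5]])
    )
    sigma2_eps: float = 1.0
    group_ranges: list[tuple[float, float]] | None = None
    family_link: str = "gaussian-identity"
    sigma2_obs: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.Sigma = validate_covariance(self.Sigma)
        if isinstance(self.group_sizes, (int, np.integer)):
            self.group_sizes = [int(self.group_sizes)] * self.n_groups
        self.group_sizes = [int(s) for s in self.group_sizes]
        if len(self.group_sizes) != self.n_groups:
            raise InputError("group_sizes length must equal n_groups")
        if any(s < 1 for s in self.group_sizes):
            raise InputError("every group size must be >= 1")
        if self.sigma2_eps < 0 or self.sigma2_obs < 0:
            raise InputError("variances must be non-negative")
        if self.family_link == "poisson-log" and self.sigma2_eps != 0:
            raise InputError("poisson-log requires sigma2_eps = 0")
        if self.family_link not in ("gaussian-identity", "poisson-log"):
            raise InputError(
                f"simulation supports gaussian-identity and poisson-log, "
                f"got '{self.family_link}'"
            )
        if self.group_ranges is not None and len(self.group_ranges) != self.n_groups:
            raise InputError("group_ranges length must equal n_groups")

    @property
    def n_total(self) -> int:
        return int(sum(self.group_sizes))

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups,
            "group_sizes": list(self.group_sizes),
            "beta": list(self.beta),
            "Sigma": np.asarray(self.Sigma).tolist(),
            "sigma2_eps": self.sigma2_eps,
            "group_ranges": (
                None
                if self.group_ranges is None
                else [list(r) for r in self.group_ranges]
            ),
            "family_link": self.family_link,
            "sigma2_obs": self.sigma2_obs,
            "seed": self.seed,
        }


def simulate_dataset(spec: SimulationSpec) -> pd.DataFrame:
    """Draw one dataset (columns: group, x, y) from the spec.

    Fully reproducible: the same spec (including seed) yields the same
    table.  Uses one numpy default_rng(seed) per call.
    """
    rng = np.random.default_rng(spec.seed)
    beta0, beta1 = spec.beta
    # eigendecomposition-based square root: works for singular Sigma
    # (e.g. a zero matrix), where a Cholesky factor does not exist
    evals, evecs = np.linalg.eigh(spec.Sigma)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    alphas = rng.standard_normal(size=(spec.n_groups, 2)) @ root.T
    rows_g, rows_x, rows_eta = [], [], []
    for j, size in enumerate(spec.group_sizes):
        lo, hi = (
            spec.group_ranges[j] if spec.group_ranges is not None else DEFAULT_RANGE
        )
        x = rng.uniform(lo, hi, size=size)
        eta = (beta0 + alphas[j, 0]) + (beta1 + alphas[j, 1]) * x
        rows_g.append(np.full(size, j))
        rows_x.append(x)
        rows_eta.append(eta)
    group = np.concatenate(rows_g)
    x = np.concatenate(rows_x)
    eta = np.concatenate(rows_eta)
    if spec.sigma2_obs > 0:
        eta = eta + rng.normal(0.0, np.sqrt(spec.sigma2_obs), size=eta.shape)
    if spec.family_link == "gaussian-identity":
        noise = (
            rng.normal(0.0, np.sqrt(spec.sigma2_eps), size=eta.shape)
            if spec.sigma2_eps > 0
            else 0.0
        )
        y = eta + noise
    else:  # poisson-log
        y = rng.poisson(np.exp(eta)).astype(float)
    return pd.DataFrame({"group": group, "x": x, "y": y})


def true_partition(spec: SimulationSpec, realized_x) -> VariancePartition:
    """Analytic variance partition at the generating parameters.

    Evaluated over the realized covariates: fixed-effect variance is the
    sample variance of beta0 + beta1 * x, the random-effect component is the
    mean of the quadratic forms [1, x_i]' Sigma [1, x_i].
    """
    x = np.asarray(realized_x, dtype=float).ravel()
    if x.size < 2:
        raise InputError("need at least 2 realized covariate values")
    beta0, beta1 = spec.beta
    eta_fixed = beta0 + beta1 * x
    sigma2_f = float(np.var(eta_fixed, ddof=1))
    Z = np.column_stack([np.ones_like(x), x])
    sigma2_bar = float(np.trace(spec.Sigma @ (Z.T @ Z))) / x.size
    sigma2_e = spec.sigma2_eps + spec.sigma2_obs
    sigma2_d = distribution_specific_variance(
        spec.family_link, float(np.mean(eta_fixed))
    )
    return VariancePartition(
        sigma2_f=sigma2_f,
        sigma2_terms=[sigma2_bar],
        sigma2_e=sigma2_e,
        sigma2_d=sigma2_d,
    )


def make_unbalanced_design(
    J: int, dominant_fraction: float, total_n: int
) -> list[int]:
    """Group sizes with one dominant group holding most observations.

    Group 1 receives ``round(dominant_fraction * total_n)`` observations;
    the remainder is split as evenly as possible over the other J-1 groups.
    Sizes always sum to ``total_n``.
    """
    if J < 2:
        raise InputError("need at least 2 groups")
    if not 0 < dominant_fraction < 1:
        raise InputError("dominant_fraction must be in (0, 1)")
    dominant = int(round(dominant_fraction * total_n))
    rest = total_n - dominant
    base, extra = divmod(rest, J - 1)
    sizes = [dominant] + [base + (1 if i < extra else 0) for i in range(J - 1)]
    if any(s < 1 for s in sizes):
        raise InputError(
            f"design infeasible: a group would get fewer than 1 observation "
            f"(sizes={sizes})"
        )
    return sizes
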