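"""R² for a Poisson GLMM from externally supplied model components.

Only Gaussian models are fitted internally; for a GLMM fitted elsewhere you
supply the estimated pieces (fixed design and estimates, random-effect
design and covariance, additive dispersion) and the family.  The
distribution-specific variance of a log-link Poisson model,
ln(1 + 1/exp(beta0)), uses beta0 = mean of the linear predictor rather
than a refit with centred covariates.
"""

import numpy as np

from r2mixed import ModelComponents, RandomEffectTerm, estimate_beta0, r2_glmm
from r2mixed.simulate import SimulationSpec, simulate_dataset

spec = SimulationSpec(
    n_groups=50,
    group_sizes=10,
    beta=(0.5, 0.3),
    Sigma=np.array([[0.4, 0.05], [0.05, 0.1]]),
    sigma2_eps=0.0,
    family_link="poisson-log",
    seed=8,
)
data = simulate_dataset(spec)

n = len(data)
x = data["x"].to_numpy()
X = np.column_stack([np.ones(n), x])
Z = np.column_stack([np.ones(n), x])
components = ModelComponents(
    X=X,
    beta=np.array(spec.beta),        # here: the generating values
    terms=[RandomEffectTerm(label="group", Z=Z, Sigma=spec.Sigma)],
    sigma2_e=0.0,
    family_link="poisson-log",
)
r2 = r2_glmm(components)
b0 = estimate_beta0(X, components.beta)

print(f"beta0 (mean linear predictor): {b0:.3f}")
print(f"sigma2_d = ln(1 + 1/exp(beta0)) = {r2.partition.sigma2_d:.3f}")
print(f"marginal R2:    {r2.marginal:.3f}")
print(f"conditional R2: {r2.conditional:.3f}")
# sigma2_d plays the role of a residual variance on the latent log scale;
# a higher baseline rate (larger beta0) shrinks it and raises both R².
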