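"""Repeatability (ICC) conditioned on a covariate value.

In a random-slopes model the between-group variance depends on the
covariate: at covariate value v it is [1, v]' Sigma [1, v].  The ICC —
between-group variance over total — therefore traces a curve over v, e.g.
phenotypic consistency as a function of age.
"""

import numpy as np

from r2mixed import RandomEffectTerm, icc_conditional

Sigma = np.array([[2.0, 0.5], [0.5, 1.0]])  # intercept var 2, slope var 1
term = RandomEffectTerm(label="id", Z=np.array([[1.0, 0.0]]), Sigma=Sigma)

values = np.linspace(0.0, 2.0, 5)
iccs = icc_conditional(term, sigma2_e=1.0, covariate_values=values)

print(" v    var_between   ICC(v)")
for v, icc in zip(values, iccs):
    var_b = np.array([1, v]) @ Sigma @ np.array([1, v])
    print(f"{v:4.1f}   {var_b:8.3f}    {icc:.3f}")
# At v=0 the ICC uses only the intercept variance (2 / (2+1) = 0.667);
# it grows with v because the slope variance adds between-group spread.
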