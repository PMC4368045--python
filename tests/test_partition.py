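import math

import numpy as np
import pytest

from r2mixed import (
    DegenerateModelError,
    InputError,
    ModelComponents,
    R2MixedError,
    RandomEffectTerm,
    VariancePartition,
    assemble_partition,
    distribution_specific_variance,
    estimate_beta0,
    fixed_effects_variance,
    icc_conditional,
    mean_random_effect_variance,
    observation_variances,
    r2_conditional,
    r2_glmm,
    r2_marginal,
)
from conftest import random_instance, random_psd
from _oracles import brute_mean_variance, brute_observation_variances

SIG = np.array([[2.0, 0.5], [0.5, 1.0]])


def term(Z, Sigma):
    return RandomEffectTerm(label="g", Z=np.asarray(Z, dtype=float), Sigma=Sigma)


class TestObservationVariances:
    @pytest.mark.parametrize(
        "row, expected",
        [([1.0, 0.0], 2.0), ([1.0, 1.0], 4.0), ([1.0, 2.0], 8.0)],
    )
    def test_quadratic_form_rows(self, row, expected):
        t = term([row], SIG)
        np.testing.assert_allclose(observation_variances(t), [expected])

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            Z, Sigma = random_instance(rng, max_n=60)
            got = observation_variances(term(Z, Sigma))
            np.testing.assert_allclose(
                got, brute_observation_variances(Z, Sigma), rtol=1e-10, atol=1e-10
            )

    def test_sigma_unset_is_error(self):
        t = RandomEffectTerm(label="g", Z=np.ones((3, 1)))
        with pytest.raises(R2MixedError, match="no Sigma"):
            observation_variances(t)


class TestMeanRandomEffectVariance:
    def test_random_intercepts_reduction_exact(self, rng):
        """Z = ones column: the mean variance is the intercept variance
        exactly, whatever n."""
        for n in (1, 2, 3, 7, 100, 999):
            s = float(rng.uniform(0.01, 5.0))
            t = term(np.ones((n, 1)), [[s]])
            assert mean_random_effect_variance(t) == s

    def test_two_point_slope_example(self):
        t = term([[1.0, 0.0], [1.0, 1.0]], SIG)
        assert mean_random_effect_variance(t) == pytest.approx(3.0, rel=1e-14)

    def test_no_intercept_example(self):
        t = term([[2.0], [4.0]], [[1.0]])
        assert mean_random_effect_variance(t) == pytest.approx(10.0, rel=1e-14)

    def test_trace_identity_property(self, rng):
        """Tr(Z Sigma Z')/n equals the mean of the observation-level
        variances and the cyclic form Tr(Sigma Z'Z)/n."""
        for _ in range(100):
            Z, Sigma = random_instance(rng)
            t = term(Z, Sigma)
            val = mean_random_effect_variance(t)
            brute = brute_mean_variance(Z, Sigma)
            assert val == pytest.approx(brute, rel=1e-12)
            assert val == pytest.approx(
                float(np.mean(observation_variances(t))), rel=1e-12
            )

    def test_covariate_scaling_law(self, rng):
        """Scaling the slope covariate by c scales a slope-only term's mean
        variance by c^2."""
        x = rng.normal(size=25)
        s = 0.7
        for c in (0.5, 2.0, -3.0):
            base = mean_random_effect_variance(term(x[:, None], [[s]]))
            scaled = mean_random_effect_variance(term(c * x[:, None], [[s]]))
            assert scaled == pytest.approx(c**2 * base, rel=1e-12)

    def test_closed_forms_at_x0_and_x1(self, rng):
        """Variance at x=0 is the intercept variance; at x=1 it is
        s00 + 2*s01 + s11, for arbitrary PSD Sigma."""
        for _ in range(25):
            Sigma = random_psd(rng, 2)
            v = observation_variances(term([[1.0, 0.0], [1.0, 1.0]], Sigma))
            assert v[0] == pytest.approx(Sigma[0, 0], rel=1e-12, abs=1e-12)
            assert v[1] == pytest.approx(
                Sigma[0, 0] + 2 * Sigma[0, 1] + Sigma[1, 1], rel=1e-12, abs=1e-12
            )


class TestFixedEffectsPieces:
    def test_constant_predictor_has_zero_variance(self):
        X = np.column_stack([np.ones(5), np.full(5, 3.0)])
        assert fixed_effects_variance(X, [1.0, 0.0]) == 0.0

    def test_sample_variance_denominator(self):
        # linear predictor [0, 1, 2]: sample variance with ddof=1 is 1
        assert fixed_effects_variance(np.array([[0.0], [1.0], [2.0]]), [1.0]) == 1.0

    def test_beta_scaling_is_quadratic(self, rng):
        X = rng.normal(size=(20, 3))
        beta = rng.normal(size=3)
        base = fixed_effects_variance(X, beta)
        assert fixed_effects_variance(X, 3.0 * beta) == pytest.approx(9 * base)

    def test_needs_two_observations(self):
        with pytest.raises(InputError):
            fixed_effects_variance(np.ones((1, 1)), [1.0])

    def test_beta0_is_mean_linear_predictor(self):
        assert estimate_beta0(np.array([[1.0], [2.0], [3.0]]), [1.0]) == 2.0
        assert estimate_beta0(np.array([[1.0], [2.0]]), [0.0]) == 0.0

    def test_beta0_equals_intercept_with_centred_covariates(self, rng):
        x = rng.normal(size=50)
        x = x - x.mean()
        X = np.column_stack([np.ones(50), x])
        beta = np.array([1.7, -2.3])
        assert estimate_beta0(X, beta) == pytest.approx(1.7, rel=1e-14)


class TestDistributionSpecificVariance:
    @pytest.mark.parametrize(
        "family, beta0, expected",
        [
            ("gaussian-identity", 5.0, 0.0),
            ("binomial-logit", 0.0, math.pi**2 / 3),
            ("binomial-probit", 0.0, 1.0),
            ("poisson-log", 0.0, math.log(2.0)),
            ("poisson-sqrt", 0.0, 0.25),
        ],
    )
    def test_family_values(self, family, beta0, expected):
        assert distribution_specific_variance(family, beta0) == pytest.approx(expected)

    def test_poisson_log_decreasing_and_vanishing(self):
        b = np.linspace(-3, 12, 40)
        vals = [distribution_specific_variance("poisson-log", bi) for bi in b]
        assert all(a > c for a, c in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.0, abs=1e-5)

    def test_unknown_family_rejected(self):
        with pytest.raises(InputError):
            distribution_specific_variance("gamma-log", 0.0)


class TestPartitionAndR2:
    def test_gaussian_intercept_only_reduction(self, rng):
        n = 40
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        beta = np.array([0.5, 1.0])
        s_alpha, s_eps = 0.8, 1.3
        comp = ModelComponents(
            X=X,
            beta=beta,
            terms=[term(np.ones((n, 1)), [[s_alpha]])],
            sigma2_e=s_eps,
        )
        part = assemble_partition(comp)
        assert part.sigma2_f == pytest.approx(np.var(X @ beta, ddof=1))
        assert part.sigma2_terms == [s_alpha]
        assert part.sigma2_e == s_eps
        assert part.sigma2_d == 0.0

    def test_poisson_total_composition(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.0, 0.2])
        comp = ModelComponents(
            X=X, beta=beta, terms=[], sigma2_e=0.0, family_link="poisson-log"
        )
        part = assemble_partition(comp)
        b0 = float(np.mean(X @ beta))
        assert part.total == pytest.approx(
            np.var(X @ beta, ddof=1) + math.log1p(math.exp(-b0))
        )

    def test_two_independent_terms_add(self, rng):
        n = 20
        x = rng.normal(size=n)
        comp = ModelComponents(
            X=np.column_stack([np.ones(n), x]),
            beta=[0.0, 1.0],
            terms=[
                term(np.ones((n, 1)), [[1.0]]),
                term(x[:, None], [[0.5]]),
            ],
            sigma2_e=1.0,
        )
        part = assemble_partition(comp)
        assert len(part.sigma2_terms) == 2
        assert part.total == pytest.approx(
            part.sigma2_f + sum(part.sigma2_terms) + 1.0
        )

    @pytest.mark.parametrize(
        "part, r2m, r2c",
        [
            (VariancePartition(1.0, [], 0.0, 0.0), 1.0, 1.0),
            (VariancePartition(0.0, [1.0], 1.0, 0.0), 0.0, 0.5),
            (VariancePartition(1.0, [3.0], 1.0, 0.0), 0.2, 0.8),
            (VariancePartition(0.3, [0.2, 0.5], 0.0, 0.0), 0.3, 1.0),
        ],
    )
    def test_r2_ratios(self, part, r2m, r2c):
        assert r2_marginal(part) == pytest.approx(r2m)
        assert r2_conditional(part) == pytest.approx(r2c)

    def test_no_random_terms_marginal_equals_conditional(self):
        part = VariancePartition(2.0, [], 1.0, 0.0)
        assert r2_marginal(part) == r2_conditional(part)

    def test_zero_total_is_degenerate(self):
        part = VariancePartition(0.0, [], 0.0, 0.0)
        with pytest.raises(DegenerateModelError):
            r2_marginal(part)
        comp = ModelComponents(
            X=np.ones((3, 1)), beta=[0.0], terms=[], sigma2_e=0.0
        )
        with pytest.raises(DegenerateModelError):
            assemble_partition(comp)

    def test_ordering_and_bounds_property(self, rng):
        """0 <= marginal <= conditional <= 1 for random valid partitions."""
        for _ in range(200):
            part = VariancePartition(
                sigma2_f=float(rng.uniform(0, 5)),
                sigma2_terms=list(rng.uniform(0, 5, size=rng.integers(0, 4))),
                sigma2_e=float(rng.uniform(0, 5)),
                sigma2_d=float(rng.choice([0.0, 1.0, math.pi**2 / 3])),
            )
            if part.total == 0:
                continue
            m, c = r2_marginal(part), r2_conditional(part)
            assert 0.0 <= m <= c <= 1.0


class TestIccConditional:
    def test_equal_components_at_intercept(self):
        t = term([[1.0, 0.0]], SIG)
        out = icc_conditional(t, sigma2_e=SIG[0, 0], covariate_values=[0.0])
        np.testing.assert_allclose(out, [0.5])

    def test_zero_sigma_gives_zero(self):
        t = term([[1.0, 0.0]], np.zeros((2, 2)))
        out = icc_conditional(t, sigma2_e=1.0, covariate_values=[-1.0, 0.0, 2.0])
        np.testing.assert_array_equal(out, [0.0, 0.0, 0.0])

    def test_worked_value_at_x1(self):
        t = term([[1.0, 0.0]], SIG)
        out = icc_conditional(t, sigma2_e=1.0, covariate_values=[1.0])
        np.testing.assert_allclose(out, [0.8])

    def test_bounds_and_divergence(self, rng):
        """ICC stays in [0,1] and tends to 1 as the group variance blows up."""
        Sigma = random_psd(rng, 2) + 0.1 * np.eye(2)
        t = term([[1.0, 0.0]], Sigma)
        vals = np.linspace(-50, 50, 21)
        out = icc_conditional(t, sigma2_e=1.0, covariate_values=vals)
        assert ((out >= 0) & (out <= 1)).all()
        far = icc_conditional(t, sigma2_e=1.0, covariate_values=[1e6])
        assert far[0] > 0.999

    def test_degenerate_zero_denominator(self):
        t = term([[1.0, 0.0]], np.zeros((2, 2)))
        with pytest.raises(DegenerateModelError):
            icc_conditional(t, sigma2_e=0.0, covariate_values=[0.0])

    def test_monte_carlo_group_effect_variance(self, rng):
        """Empirical variance of a0 + a1*v over MVN draws matches the
        quadratic-form variance within 3 standard errors."""
        Sigma = np.array([[1.0, 0.25], [0.25, 0.5]])
        v = 0.7
        ndraw = 100_000
        a = rng.multivariate_normal(np.zeros(2), Sigma, size=ndraw)
        eff = a[:, 0] + a[:, 1] * v
        emp = eff.var(ddof=1)
        truth = float(np.array([1, v]) @ Sigma @ np.array([1, v]))
        # variance of a sample variance of a normal: 2 sigma^4 / (n - 1)
        se = math.sqrt(2.0 * truth**2 / (ndraw - 1))
        assert abs(emp - truth) < 3 * se
        icc = icc_conditional(term([[1.0, 0.0]], Sigma), 1.0, covariate_values=[v])
        assert icc[0] == pytest.approx(truth / (truth + 1.0))

    def test_r2_glmm_wrapper_consistency(self, rng):
        n = 30
        x = rng.normal(size=n)
        comp = ModelComponents(
            X=np.column_stack([np.ones(n), x]),
            beta=[0.5, 1.0],
            terms=[term(np.column_stack([np.ones(n), x]), SIG)],
            sigma2_e=1.0,
        )
        res = r2_glmm(comp)
        assert res.marginal == pytest.approx(r2_marginal(res.partition))
        assert res.conditional == pytest.approx(r2_conditional(res.partition))
        assert 0 <= res.marginal <= res.conditional <= 1
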