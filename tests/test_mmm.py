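"""Stacked joint inference: covariances, MVN quantiles, adjustments, CIs."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import norm

from multibin import (
    DesignSpec,
    MMMUnavailable,
    StackedInference,
    adjust_mmm,
    bonferroni,
    correlation_matrix,
    critical_value,
    fit_logit,
    generate_scenario,
    max_abs_mvn_prob,
    regression_scenario,
    simultaneous_ci,
    stack,
    stack_covariance,
    stack_covariance_alt,
)
from tests.conftest import simulate_logit_response


def fitted_family(seed=2024, slopes=(0.12, 0.08, 0.0, 0.0, 0.0)):
    sc = regression_scenario(
        n=200, n_endpoints=len(slopes), pi0=0.25, rho=0.5, slopes=list(slopes)
    )
    data = generate_scenario(sc, seed)
    design = DesignSpec("regression", data.dose)
    return data, [
        fit_logit(data.Y[:, j], design, label=l)
        for j, l in enumerate(data.labels)
    ]


class TestStackedCovariance:
    def test_single_endpoint_equals_sandwich_oracle(self, dose200):
        rng = np.random.default_rng(1)
        design = DesignSpec("regression", dose200)
        y = simulate_logit_response(rng, design.matrix(), [-1.0, 0.1])
        fit = fit_logit(y, design)
        sigma = stack_covariance([fit])
        ref = sm.GLM(y, design.matrix(), family=sm.families.Binomial()).fit(
            cov_type="HC0"
        )
        np.testing.assert_allclose(
            sigma / len(y), ref.cov_params(), atol=1e-8
        )

    def test_plain_and_bread_meat_forms_agree(self):
        _, fits = fitted_family()
        np.testing.assert_allclose(
            stack_covariance(fits), stack_covariance_alt(fits), atol=1e-8
        )

    def test_duplicated_endpoint_has_correlation_one(self, dose200):
        rng = np.random.default_rng(2)
        design = DesignSpec("regression", dose200)
        y = simulate_logit_response(rng, design.matrix(), [-1.0, 0.1])
        fits = [fit_logit(y, design, label=l) for l in ("a", "b")]
        st = stack(fits)
        assert st.R[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_independent_endpoints_have_small_correlation(self):
        rng = np.random.default_rng(3)
        n = 10_000
        dose = np.tile([0.0, 2.5, 5.0, 10.0], n // 4)
        design = DesignSpec("regression", dose)
        X = design.matrix()
        fits = [
            fit_logit(simulate_logit_response(rng, X, [-1.0, 0.0]), design, label=f"e{j}")
            for j in range(3)
        ]
        st = stack(fits)
        off = st.R[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_mismatched_n_rejected(self, dose200):
        design_a = DesignSpec("regression", dose200)
        design_b = DesignSpec("regression", dose200[:100])
        fa = fit_logit(np.tile([0.0, 1.0], 100), design_a)
        fb = fit_logit(np.tile([0.0, 1.0], 50), design_b)
        with pytest.raises(ValueError, match="same N"):
            stack_covariance([fa, fb])


class TestCorrelationMatrix:
    def test_diagonal_covariance_gives_identity(self):
        np.testing.assert_allclose(
            correlation_matrix(np.diag([4.0, 9.0, 0.25])), np.eye(3)
        )

    def test_two_by_two_arithmetic(self):
        r = correlation_matrix(np.array([[4.0, 2.0], [2.0, 4.0]]))
        assert r[0, 1] == pytest.approx(0.5)

    def test_negative_diagonal_raises_unavailable(self):
        with pytest.raises(MMMUnavailable):
            correlation_matrix(np.array([[1.0, 0.0], [0.0, -2.0]]))

    def test_nonfinite_diagonal_raises_unavailable(self):
        with pytest.raises(MMMUnavailable):
            correlation_matrix(np.array([[np.inf, 0.0], [0.0, 1.0]]))


Z_975 = 1.959963984540054


class TestMvnRectangle:
    def test_univariate_closed_form(self):
        assert max_abs_mvn_prob(Z_975, np.eye(1)) == pytest.approx(0.95, abs=1e-9)

    @pytest.mark.parametrize("c", [1.0, 2.0, 2.5])
    def test_bivariate_independence_product(self, c):
        expected = (2 * norm.cdf(c) - 1) ** 2
        assert max_abs_mvn_prob(c, np.eye(2)) == pytest.approx(expected, abs=1e-8)

    def test_perfect_dependence_collapses_to_univariate(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert max_abs_mvn_prob(2.0, R) == pytest.approx(
            2 * norm.cdf(2.0) - 1, abs=1e-8
        )

    def test_qmc_path_matches_independence_product(self):
        expected = (2 * norm.cdf(2.2) - 1) ** 5
        assert max_abs_mvn_prob(2.2, np.eye(5)) == pytest.approx(expected, abs=1e-4)

    def test_reproducible(self):
        R = np.full((4, 4), 0.6)
        np.fill_diagonal(R, 1.0)
        assert max_abs_mvn_prob(2.0, R) == max_abs_mvn_prob(2.0, R)


class TestCriticalValue:
    def test_univariate_is_normal_quantile(self):
        assert critical_value(0.05, np.eye(1)) == pytest.approx(Z_975, abs=1e-5)

    @pytest.mark.parametrize("m", [2, 5, 10])
    def test_identity_correlation_matches_sidak(self, m):
        sidak = norm.ppf((1 + 0.95 ** (1 / m)) / 2)
        assert critical_value(0.05, np.eye(m)) == pytest.approx(sidak, abs=1e-4)

    def test_monotone_in_family_size(self):
        c1 = critical_value(0.05, np.eye(1))
        c2 = critical_value(0.05, np.eye(2))
        c10 = critical_value(0.05, np.eye(10))
        assert c1 < c2 < c10


def make_stacked(t, R):
    t = np.asarray(t, dtype=float)
    return StackedInference(
        estimates=t.copy(),
        se=np.ones_like(t),
        t=t,
        R=np.asarray(R, dtype=float),
        sigma=R,
        sigma_alt=R,
        labels=tuple(f"h{i}" for i in range(len(t))),
        n=100,
    )


class TestAdjustments:
    @pytest.mark.parametrize("m", [2, 5, 10])
    def test_identity_correlation_reduces_to_sidak(self, m):
        t = np.linspace(0.5, 2.8, m)
        res = adjust_mmm(make_stacked(t, np.eye(m)))
        p_raw = 2 * norm.sf(np.abs(t))
        sidak = 1 - (1 - p_raw) ** m
        np.testing.assert_allclose(res.p_adj, sidak, atol=1e-4)

    def test_single_hypothesis_adjusted_equals_raw(self):
        res = adjust_mmm(make_stacked([1.7], np.eye(1)))
        assert res.p_adj[0] == pytest.approx(res.p_raw[0], abs=1e-9)

    def test_bracketed_by_raw_and_bonferroni(self):
        _, fits = fitted_family(seed=5)
        st = stack(fits)
        res = adjust_mmm(st)
        m = st.m
        assert np.all(res.p_adj >= res.p_raw - 1e-12)
        assert np.all(res.p_adj <= np.minimum(m * res.p_raw, 1.0) + 1e-4)

    def test_correlation_makes_mmm_beat_bonferroni(self):
        R = np.full((5, 5), 0.8)
        np.fill_diagonal(R, 1.0)
        t = np.full(5, 2.2)
        res = adjust_mmm(make_stacked(t, R))
        p_bonf = np.minimum(5 * 2 * norm.sf(2.2), 1.0)
        assert np.all(res.p_adj < p_bonf - 0.01)

    def test_bonferroni_examples(self):
        res = bonferroni(np.array([0.01, 0.5, 0.0]), 10)
        np.testing.assert_allclose(res.p_adj, [0.1, 1.0, 0.0])

    def test_bonferroni_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([1.2]), 2)


class TestSimultaneousCI:
    def test_single_parameter_is_wald_interval(self):
        st = make_stacked([1.0], np.eye(1))
        lo, hi, c = simultaneous_ci(st, 0.05)
        assert c == pytest.approx(Z_975, abs=1e-5)
        assert lo[0] == pytest.approx(1.0 - Z_975, abs=1e-4)

    def test_contains_marginal_interval(self):
        _, fits = fitted_family(seed=8)
        st = stack(fits)
        lo, hi, c = simultaneous_ci(st, 0.05)
        assert c >= Z_975
        np.testing.assert_array_less(lo, st.estimates - Z_975 * st.se + 1e-12)

    def test_duality_with_adjusted_pvalues(self):
        _, fits = fitted_family(seed=8)
        st = stack(fits)
        res = adjust_mmm(st, alpha=0.05)
        lo, hi, _ = simultaneous_ci(st, 0.05)
        excludes_zero = (lo > 0) | (hi < 0)
        # ignore knife-edge cases within the MVN integration tolerance
        decided = np.abs(res.p_adj - 0.05) > 2e-3
        np.testing.assert_array_equal(
            excludes_zero[decided], (res.p_adj < 0.05)[decided]
        )


class TestReferenceImplementationParity:
    """Frozen expectations computed with R multcomp (mmm + glht) on the same
    dataset: five endpoints, N=200, doses {0,2.5,5,10}, slopes
    (0.12, 0.08, 0, 0, 0), within-family correlation 0.5, seed 2024."""

    MULTCOMP_P = np.array(
        [0.05855621, 0.05865140, 0.81144819, 0.21240984, 0.17402573]
    )
    MULTCOMP_EST = np.array(
        [0.09955924, 0.10110270, -0.04951832, -0.10187451, -0.11042939]
    )
    MULTCOMP_SE = np.array(
        [0.04011847, 0.04076657, 0.04989780, 0.05264610, 0.05438862]
    )
    MULTCOMP_CALPHA = 2.541391

    def test_adjusted_pvalues_match_multcomp(self):
        _, fits = fitted_family(seed=2024)
        st = stack(fits)
        np.testing.assert_allclose(st.estimates, self.MULTCOMP_EST, atol=1e-6)
        np.testing.assert_allclose(st.se, self.MULTCOMP_SE, atol=1e-6)
        res = adjust_mmm(st)
        np.testing.assert_allclose(res.p_adj, self.MULTCOMP_P, atol=5e-3)

    def test_critical_value_matches_multcomp(self):
        _, fits = fitted_family(seed=2024)
        st = stack(fits)
        assert critical_value(0.05, st.R) == pytest.approx(
            self.MULTCOMP_CALPHA, abs=5e-3
        )
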