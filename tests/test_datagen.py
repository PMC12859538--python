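"""Correlated-binary generator: intensities, marginals, correlations, streams."""

import math

import numpy as np
import pytest

from multibin import (
    BinaryEndpointData,
    CorrelatedBinarySpec,
    InfeasibleCorrelationError,
    Scenario,
    generate,
    generate_scenario,
    regression_scenario,
    shared_intensity,
)


def equicorr_spec(j: int, pi: float, rho: float) -> CorrelatedBinarySpec:
    corr = np.full((j, j), rho)
    np.fill_diagonal(corr, 1.0)
    return CorrelatedBinarySpec(probs=np.full(j, pi), corr=corr)


class TestSharedIntensity:
    def test_independence_gives_zero(self):
        assert shared_intensity(0.0, 0.3, 0.7) == 0.0

    def test_symmetric_half_case_closed_form(self):
        # pi_j = pi_k = 0.5 makes the odds ratio q/pi equal to 1, so
        # lambda = ln(1 + rho) = ln(1.5)
        assert shared_intensity(0.5, 0.5, 0.5) == pytest.approx(
            math.log(1.5), abs=1e-12
        )

    def test_unrepresentable_negative_correlation_raises(self):
        # 1 + (-0.2) * sqrt(0.9*0.9/(0.1*0.1)) = 1 - 1.8 < 0
        with pytest.raises(InfeasibleCorrelationError):
            shared_intensity(-0.2, 0.1, 0.1)

    @pytest.mark.parametrize("pi", [0.0, 1.0, -0.1])
    def test_probabilities_outside_open_interval_rejected(self, pi):
        with pytest.raises(ValueError):
            shared_intensity(0.3, pi, 0.5)


class TestSpecValidation:
    def test_asymmetric_corr_rejected(self):
        corr = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            CorrelatedBinarySpec(probs=[0.3, 0.3], corr=corr)

    def test_negative_offdiagonal_rejected(self):
        corr = np.array([[1.0, -0.3], [-0.3, 1.0]])
        with pytest.raises(ValueError):
            CorrelatedBinarySpec(probs=[0.3, 0.3], corr=corr)

    def test_jointly_infeasible_correlations_name_endpoint(self):
        # two strong pairs competing for endpoint 0's total intensity
        corr = np.array(
            [[1.0, 0.9, 0.9], [0.9, 1.0, 0.0], [0.9, 0.0, 1.0]]
        )
        with pytest.raises(InfeasibleCorrelationError, match=r"endpoint\(s\)"):
            CorrelatedBinarySpec(probs=[0.5, 0.5, 0.5], corr=corr)


class TestGenerate:
    def test_independent_endpoints_uncorrelated(self):
        spec = equicorr_spec(2, 0.25, 0.0)
        y = generate(spec, 100_000, seed_or_rng := 7)
        c = np.corrcoef(y.T)[0, 1]
        assert abs(c) < 0.02

    @pytest.mark.parametrize("pi", [0.25, 0.5])
    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_mean_pairwise_correlation_recovers_target(self, pi, rho):
        """Average empirical correlation over many small datasets hits rho."""
        spec = equicorr_spec(2, pi, rho)
        reps, n = 3000, 200
        ss = np.random.SeedSequence(42)
        rng = np.random.default_rng(ss)
        cors = np.empty(reps)
        means = np.empty((reps, 2))
        for r in range(reps):
            y = generate(spec, n, rng)
            means[r] = y.mean(axis=0)
            cors[r] = np.corrcoef(y.T)[0, 1]
        assert abs(np.mean(cors) - rho) < 0.02
        assert np.all(np.abs(means.mean(axis=0) - pi) < 0.01)

    def test_marginal_recovery_within_binomial_error(self):
        spec = equicorr_spec(5, 0.25, 0.5)
        n = 50_000
        y = generate(spec, n, 123)
        tol = 4.0 * math.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(y.mean(axis=0) - 0.25) < tol)

    def test_probability_near_one_gives_all_ones(self):
        spec = CorrelatedBinarySpec(
            probs=[1 - 1e-12, 1 - 1e-12], corr=np.eye(2)
        )
        assert generate(spec, 1000, 5).all()

    def test_deterministic_given_seed(self):
        spec = equicorr_spec(3, 0.3, 0.4)
        a = generate(spec, 500, 99)
        b = generate(spec, 500, 99)
        np.testing.assert_array_equal(a, b)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            generate(equicorr_spec(2, 0.5, 0.0), 0, 1)


class TestScenario:
    def test_null_scenario_constant_probability_across_groups(self):
        sc = regression_scenario(n=40_000, n_endpoints=2, pi0=0.25, rho=0.0)
        data = generate_scenario(sc, 1)
        for level in np.unique(data.dose):
            rate = data.Y[data.dose == level].mean()
            assert rate == pytest.approx(0.25, abs=0.02)

    def test_power_scenario_control_rate_matches_intercept(self):
        """Intercept logit(0.1) puts the dose-0 event rate at 10%."""
        sc = regression_scenario(
            n=400, n_endpoints=4, pi0=0.1, rho=0.5, slopes=0.15,
            n_alternative=2,
        )
        rates = []
        for seed in range(300):
            data = generate_scenario(sc, seed)
            rates.append(data.Y[data.dose == 0.0].mean())
        assert np.mean(rates) == pytest.approx(0.1, abs=0.01)

    def test_cross_block_correlation_is_null(self):
        """Null and alternative blocks come from independent streams."""
        sc = regression_scenario(
            n=200, n_endpoints=4, pi0=0.25, rho=0.9, slopes=0.0,
            n_alternative=2,
        )
        cross = []
        within = []
        for seed in range(800):
            y = generate_scenario(sc, seed).Y
            c = np.corrcoef(y.T)
            cross.extend([c[0, 2], c[0, 3], c[1, 2], c[1, 3]])
            within.extend([c[0, 1], c[2, 3]])
        assert abs(np.mean(cross)) < 0.02
        assert np.mean(within) == pytest.approx(0.9, abs=0.02)

    def test_null_block_unchanged_when_alternative_grows(self):
        """Adding endpoints to one block never perturbs the other's stream."""
        small = regression_scenario(
            n=80, n_endpoints=4, pi0=0.25, rho=0.5, slopes=0.1, n_alternative=2
        )
        big = regression_scenario(
            n=80, n_endpoints=5, pi0=0.25, rho=0.5, slopes=0.1, n_alternative=3
        )
        y_small = generate_scenario(small, 77).Y
        y_big = generate_scenario(big, 77).Y
        np.testing.assert_array_equal(y_small[:, 2:4], y_big[:, 3:5])

    def test_invalid_blocks_rejected(self):
        with pytest.raises(ValueError, match="zero effects"):
            Scenario(
                kind="regression",
                dose_levels=(0.0, 2.5, 5.0, 10.0),
                n=40,
                intercepts=[0.0, 0.0],
                effects=[[0.3], [0.0]],
                rho=0.0,
                null_block=(0,),
                alt_block=(1,),
            )

    def test_data_container_rejects_nonbinary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            BinaryEndpointData(
                Y=np.array([[0, 2], [1, 0]]), dose=[0.0, 1.0], labels=("a", "b")
            )
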