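import numpy as np
import pytest

from multibin import DesignSpec


@pytest.fixture
def dose200() -> np.ndarray:
    """Four dose levels, 50 individuals each: the standard balanced design."""
    return np.tile([0.0, 2.5, 5.0, 10.0], 50)


@pytest.fixture
def regression_design(dose200) -> DesignSpec:
    return DesignSpec("regression", dose200)


def simulate_logit_response(rng: np.random.Generator, X: np.ndarray, beta) -> np.ndarray:
    """Independent Bernoulli draws from a logistic model (test helper)."""
    from scipy.special import expit

    return rng.binomial(1, expit(X @ np.asarray(beta, dtype=float))).astype(float)
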