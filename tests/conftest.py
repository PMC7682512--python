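import numpy as np
import pytest

import riskpanel as rp


@pytest.fixture(scope="session")
def two_by_two():
    return rp.toy_fixture("two_by_two")


@pytest.fixture(scope="session")
def eight_by_four():
    return rp.toy_fixture("eight_by_four")


@pytest.fixture(scope="session")
def m2_model():
    """Small correlated two-outcome model with a moderately informative predictor."""
    sigma_l = np.array([[1.0, 0.5], [0.5, 1.0]])
    sigma_x = np.array([[0.3, 0.1], [0.1, 0.2]])
    return rp.LiabilityProbitModel([0.1, 0.3], sigma_l, sigma_x, sigma_x)


@pytest.fixture(scope="session")
def m3_model():
    """Three-outcome model with common prevalences so every sense has support."""
    corr = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]])
    sigma_x = corr * np.outer(np.sqrt([0.25, 0.15, 0.35]), np.sqrt([0.25, 0.15, 0.35]))
    return rp.LiabilityProbitModel([0.2, 0.3, 0.15], corr, sigma_x, sigma_x)


@pytest.fixture(scope="session")
def m3_cohort(m3_model):
    return rp.simulate_cohort(m3_model, 100_000, seed=20200629)


def random_panel(rng, n=60, m=3, informative=True):
    """Arbitrary valid panel for property tests."""
    outcomes = (rng.random((n, m)) < rng.uniform(0.2, 0.6, size=m)).astype(int)
    noise = rng.random((n, m))
    risks = 0.6 * outcomes + 0.4 * noise if informative else noise
    thresholds = rng.uniform(0.2, 0.8, size=m)
    return rp.validate_panel(outcomes, np.clip(risks, 0, 1), thresholds)
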