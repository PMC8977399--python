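import numpy as np
import pytest

from snbrecal import CohortData, DecisionPolicy


@pytest.fixture
def toy_cohort() -> CohortData:
    """Eight subjects with hand-countable threshold exceedances."""
    cases = [0.9, 0.6, 0.35, 0.2]
    controls = [0.8, 0.3, 0.25, 0.1]
    return CohortData(
        y=np.r_[np.ones(4), np.zeros(4)],
        s=np.r_[cases, controls],
    )


@pytest.fixture
def policy() -> DecisionPolicy:
    return DecisionPolicy(R=0.3)


@pytest.fixture
def separated_cohort() -> CohortData:
    """All case scores strictly above all control scores."""
    rng = np.random.default_rng(7)
    s_case = rng.uniform(0.6, 0.95, 40)
    s_ctrl = rng.uniform(0.05, 0.4, 60)
    return CohortData(
        y=np.r_[np.ones(40), np.zeros(60)],
        s=np.r_[s_case, s_ctrl],
    )


def calibrated_cohort(n: int, seed: int) -> CohortData:
    """Scores equal to true risks: y ~ Bernoulli(s)."""
    rng = np.random.default_rng(seed)
    s = rng.beta(2, 5, n)
    y = rng.binomial(1, s)
    return CohortData(y=y, s=s)


@pytest.fixture
def calibrated_midsize() -> CohortData:
    return calibrated_cohort(2000, 11)
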