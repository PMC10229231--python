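import numpy as np
import pytest

from rescuekit import DurationDistribution, GrowthLaw, ModelParams


@pytest.fixture(scope="session")
def baseline() -> ModelParams:
    """Baseline parameter set: b_WF=1, b_WH=0, d_W=0.1, b_M=1, d_M=0.1,
    mu=1e-3, K=100 (equilibrium size 90, tau_0H ~ 45)."""
    return ModelParams()


@pytest.fixture(scope="session")
def baseline_no_mutation() -> ModelParams:
    return ModelParams(mu=0.0)


@pytest.fixture(scope="session")
def tau0h(baseline) -> float:
    return baseline.tau_0H


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


ALL_GROWTH_LAWS = [
    GrowthLaw("logistic"),
    GrowthLaw("gompertz"),
    GrowthLaw("richards", 2.0),
    GrowthLaw("richards", 0.5),
]
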