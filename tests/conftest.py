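import pytest
from hypothesis import settings

from desperation import ModelParams, solve_policy

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_policy(default_params):
    """Optimal policy and value function at the canonical defaults."""
    return solve_policy(default_params)


@pytest.fixture(scope="session")
def cheap_params() -> ModelParams:
    """Coarse grids and a small population, for structural tests where
    the fine default discretisation is not the point."""
    return ModelParams(s_steps=201, p_steps=51, N=100, T=20)
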