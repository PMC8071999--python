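import numpy as np
import pytest

from watermaze import synthetic


@pytest.fixture(scope="session")
def env():
    return synthetic.build_environment(seed=1)


@pytest.fixture(scope="session")
def schedule(env):
    return synthetic.build_schedule(env, seed=1)


@pytest.fixture(scope="session")
def small_dataset(env, schedule):
    """Two subjects per group, full 77-trial schedule, with trajectories."""
    params = {"young": synthetic.AgentParams(sigma=0.6, w=0.46),
              "old": synthetic.AgentParams(sigma=0.9, w=0.40)}
    return synthetic.simulate_responses(env, schedule, params,
                                        {"young": 2, "old": 2}, seed=11)
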