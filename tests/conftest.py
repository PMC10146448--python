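import numpy as np
import pytest

from pavlearn import TaskConfig, make_oracle_agent, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return TaskConfig()


@pytest.fixture
def oracle_session(default_config):
    """One 40-trial session driven by the always-correct agent."""
    rng = np.random.default_rng(7)
    return simulate_session(make_oracle_agent(), default_config, rng)


def simulate_many(n_sessions, config=None, seed=0, agent_factory=make_oracle_agent):
    rng = np.random.default_rng(seed)
    config = config or TaskConfig()
    return [simulate_session(agent_factory(), config, rng) for _ in range(n_sessions)]
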