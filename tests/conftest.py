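import numpy as np
import pytest

from rangerecon.types import GridSpec, ScenarioConfig


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A 60x60 scenario with reduced occurrence counts: large enough for the
    SDM to learn the niche, small enough for fast tests."""
    return ScenarioConfig(grid=GridSpec(60, 60), seed=7,
                          occurrences_per_period=(250, 180, 110, 60))


@pytest.fixture(scope="session")
def small_scenario(small_config):
    from rangerecon.synth import simulate_scenario
    return simulate_scenario(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
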