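import numpy as np
import pytest

from kidneyalloc import EngineConfig, PopulationParameters


@pytest.fixture
def region6() -> PopulationParameters:
    """Region-6 blood-type-A queue: the reference supply/demand setting."""
    return PopulationParameters(lambda_patients=378.0, mu_kidneys=270.0)


@pytest.fixture
def small_config() -> EngineConfig:
    """A short run for fast structural tests."""
    return EngineConfig(horizon_months=60.0, warmup_months=12.0,
                        initial_waitlist_size=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
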