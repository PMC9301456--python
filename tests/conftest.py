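import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pestdet import synth, voc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry() -> voc.ClassRegistry:
    return voc.ClassRegistry.maize_pests()


@pytest.fixture(scope="session")
def small_config() -> synth.SceneConfig:
    return synth.SceneConfig.small()


@pytest.fixture(scope="session")
def scene_pool(small_config) -> synth.ScenePool:
    """Eight small synthetic trap scenes shared across tests."""
    return synth.generate_dataset(small_config, 8, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
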