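import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fourcat import (
    digest_genome,
    default_model,
    default_scenarios,
    default_viewpoints,
    default_windows,
    random_genome,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_fmap():
    """The 2 Mb synthetic cis region digested at GATC (shared, seed 0)."""
    return digest_genome(random_genome(length=2_000_000, seed=0))


@pytest.fixture(scope="session")
def study():
    """Default study objects: viewpoints, windows, model, scenarios."""
    return {
        "viewpoints": default_viewpoints(),
        "windows": default_windows(),
        "model": default_model(),
        "scenarios": default_scenarios(),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20160913)
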