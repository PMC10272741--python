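import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orchardvision import SceneSpec, generate_scene

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_spec(seed: int = 7, **overrides) -> SceneSpec:
    """A scaled-down scene (256 x 156) for fast unit tests."""
    kw = dict(width=256, height=156, grape_cluster_count=3, vine_gap_count=2,
              shadow_count=2, seed=seed)
    kw.update(overrides)
    return SceneSpec(**kw)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(small_spec())


@pytest.fixture(scope="session")
def default_scene():
    """One full-size scene at the default study conditions."""
    return generate_scene(SceneSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
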