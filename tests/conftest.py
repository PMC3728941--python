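import numpy as np
import pytest

from ridleyforage import habitat_glm, synthetic


@pytest.fixture(scope="session")
def env():
    """One shared synthetic Gulf-like environment for the whole suite."""
    return synthetic.generate_environment(seed=2)


@pytest.fixture(scope="session")
def grid(env):
    """The 25-km analysis grid over the shared environment."""
    return habitat_glm.build_grid(env, release_points=[synthetic.DEFAULT_RELEASE])


@pytest.fixture(scope="session")
def shelf_point(env):
    """A lon/lat point on the shelf (inside the -100..0 m band)."""
    lon, lat = -94.0, 28.8
    assert -100.0 <= env.bathymetry.sample(lon, lat) <= 0.0
    return lon, lat


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
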