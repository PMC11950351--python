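import numpy as np
import pytest

import hanppcube as h


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world reused by read-only tests."""
    cfg = h.WorldConfig(
        seed=7,
        grid=h.GridSpec(n_rows=30, n_cols=30, cell_size=0.5, origin_lat=60.0, origin_lon=0.0),
        n_countries=3,
        years=(2000, 2004),
    )
    return h.make_world(cfg)


@pytest.fixture(scope="session")
def small_cube(small_world):
    return h.build_cube(small_world)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
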