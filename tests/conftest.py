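import warnings

import numpy as np
import pytest

from chromotif import SyntheticConfig, generate_world
from chromotif.motif import background_from_gc


@pytest.fixture(scope="session")
def bg37():
    """Yeast-like background at 37% GC."""
    return background_from_gc(0.37)


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture(scope="session")
def small_world():
    """One small two-condition world shared by read-only tests."""
    cfg = SyntheticConfig(n_genes=300, n_tfs=5, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_world(cfg)


def make_world(**kwargs):
    defaults = dict(n_genes=300, n_tfs=5, seed=0, two_conditions=False)
    defaults.update(kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_world(SyntheticConfig(**defaults))


@pytest.fixture
def world_factory():
    return make_world
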