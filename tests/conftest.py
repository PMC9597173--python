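import numpy as np
import pytest

from methkin import synthgen


@pytest.fixture(scope="session")
def small_sites():
    """A modest CGI-like site map with landscape and features, fixed seed."""
    positions = synthgen.gen_cpg_positions(5_000, 10, seed=123)
    landscape = synthgen.gen_landscape(positions, corr_length=500.0,
                                       meth_mean=0.8, seed=124)
    features = synthgen.gen_feature_tracks(positions, landscape, seed=125)
    return positions, landscape, features


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
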