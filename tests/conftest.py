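import numpy as np
import pytest

import pbdw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shepp64():
    return pbdw.make_shepp_logan(64)


@pytest.fixture(scope="session")
def shepp128():
    return pbdw.make_shepp_logan(128)


@pytest.fixture(scope="session")
def mask64_30():
    return pbdw.make_mask((64, 64), pattern="variable_density_random",
                          fraction=0.3, seed=0)


@pytest.fixture(scope="session")
def kspace64(shepp64, mask64_30):
    return pbdw.simulate_kspace(shepp64, mask64_30)


@pytest.fixture(scope="session")
def fast_config():
    """Short continuation schedule for solver tests where quality is not
    the point."""
    return pbdw.SolverConfig(mu_max=2.0**12, max_inner_iters=20)
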