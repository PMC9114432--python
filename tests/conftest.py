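import numpy as np
import pytest

import mortisesim as ms

# coarse resolutions for structural tests where sub-0.1 mm accuracy is not
# the point (keeps the suite fast; accuracy-sensitive tests use defaults)
COARSE = dict(n_phi_fibula=48, n_phi_tibia=64)


@pytest.fixture(scope="session")
def specimen():
    """One default-parameter specimen at default mesh resolution."""
    return ms.generate_specimen()


@pytest.fixture(scope="session")
def coarse_specimen():
    return ms.generate_specimen(**COARSE)


@pytest.fixture(scope="session")
def small_cohort():
    return ms.generate_cohort(6, seed=11, **COARSE)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
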