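import numpy as np
import pytest

from asmdkit.systems import make_analytic_system, make_hairpin_system


@pytest.fixture(scope="session")
def hairpin():
    """Wild-type coarse-grained hairpin (system, provider)."""
    return make_hairpin_system()


@pytest.fixture(scope="session")
def harmonic_well():
    """Single-bead harmonic benchmark centered at z = 2 Å."""
    return make_analytic_system("harmonic", k=2.0, x0=2.0, z_init=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
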