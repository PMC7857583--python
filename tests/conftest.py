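import numpy as np
import pytest

from hhlsim.cable import FiberMorphology, build_cable
from hhlsim.frontend import load_frontend_params


@pytest.fixture(scope="session")
def frontend_params():
    return load_frontend_params()


@pytest.fixture(scope="session")
def control_grid():
    """Normal-fiber grid (L_u = 10 um, L_h = 1 um)."""
    return build_cable(FiberMorphology())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
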