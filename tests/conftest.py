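import numpy as np
import pytest

from dwikit import phantom


@pytest.fixture(scope="session")
def scheme_2shell():
    """Two nonzero shells (b = 1000 / 2500 s/mm^2), enough for DKI."""
    return phantom.make_scheme([(1000.0, 30), (2500.0, 30)], n_b0=4, seed=0)


@pytest.fixture(scope="session")
def scheme_1shell():
    """Single-shell DTI scheme (b = 1000 s/mm^2)."""
    return phantom.make_scheme([(1000.0, 30)], n_b0=3, seed=2)


@pytest.fixture(scope="session")
def wm_tensor():
    """A prolate white-matter-like diffusion tensor [mm^2/s]."""
    return np.diag([1.7e-3, 0.4e-3, 0.4e-3])
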