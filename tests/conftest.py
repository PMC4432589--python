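import numpy as np
import pytest

from tmgeom.structure import AtomSelection
from tmgeom.synth import HelixSpec, make_helix


@pytest.fixture
def straight_helix():
    return make_helix(HelixSpec(n_res=30))


@pytest.fixture
def bent_helix_30deg():
    return make_helix(HelixSpec(n_res=30, bend_angle=30.0, hinge_index=15))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish proper rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def all_ca():
    return AtomSelection.ca()
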