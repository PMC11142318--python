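import numpy as np
import pytest

from poseval import fixtures as fx


@pytest.fixture(scope="session")
def ethanol_complex():
    return fx.make_reference_complex(3, "ethanol")


@pytest.fixture(scope="session")
def benzene_complex():
    return fx.make_reference_complex(4, "benzene")


@pytest.fixture(scope="session")
def acetate_complex():
    return fx.make_reference_complex(5, "acetate")


@pytest.fixture(scope="session")
def all_reference_complexes():
    return {t: fx.make_reference_complex(7, t) for t in fx.LIGAND_TEMPLATES}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rigid(rng):
    """A random proper rotation + translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return Q, t
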