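import numpy as np
import pytest

from guidearray import designer, simreads
from guidearray.overhangs import FidelityMatrix, default_overhang_set


@pytest.fixture(scope="session")
def refs():
    return designer.default_reference_set()


@pytest.fixture(scope="session")
def spacers10():
    rng = np.random.default_rng(101)
    return [simreads.random_spacer(rng) for _ in range(10)]


@pytest.fixture(scope="session")
def design10(spacers10):
    """A 10-unit array design under the bundled defaults."""
    return designer.design_array(spacers10)


@pytest.fixture(scope="session")
def design3():
    rng = np.random.default_rng(33)
    return designer.design_array([simreads.random_spacer(rng) for _ in range(3)])


@pytest.fixture(scope="session")
def pool10(design10):
    """Named spacer pool matching the 10-unit design."""
    return dict(zip(design10.names, design10.spacers))


def identity_matrix(labels):
    return FidelityMatrix(list(labels), np.eye(len(labels)) * 1000.0)


@pytest.fixture(scope="session")
def design_identity_matrix(design10):
    return identity_matrix(list(design10.overhangs))


@pytest.fixture(scope="session")
def default_set():
    return default_overhang_set()
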