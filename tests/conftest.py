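import numpy as np
import pytest

from epistasim.dynamics import HaplotypeState, state_from_allele_freqs
from epistasim.gpmaps import build_catalogue, make_parametric_map


@pytest.fixture(scope="session")
def catalogue():
    return build_catalogue()


@pytest.fixture(scope="session")
def axa_map():
    return make_parametric_map("axa", c=0.5)


@pytest.fixture(scope="session")
def additive_map():
    return make_parametric_map("additive")


@pytest.fixture(scope="session")
def neutral_map():
    return make_parametric_map("neutral")


@pytest.fixture
def le_state():
    """Linkage-equilibrium state at p = q = 0.5, unlinked loci."""
    return HaplotypeState(np.array([0.25, 0.25, 0.25, 0.25]), c=0.5)


@pytest.fixture
def coupled_state():
    """Mild coupling LD: x = (0.3, 0.2, 0.2, 0.3)."""
    return HaplotypeState(np.array([0.3, 0.2, 0.2, 0.3]), c=0.5)


@pytest.fixture(scope="session")
def freq_grid_states():
    """The 25 standard starting states (HWE, LE)."""
    grid = (0.1, 0.3, 0.5, 0.7, 0.9)
    return [state_from_allele_freqs(pA, pB, 0.0) for pA in grid for pB in grid]
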