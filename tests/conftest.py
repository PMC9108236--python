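import numpy as np
import pytest

from gdmtarget.core import BinaryStructure, Grid
from gdmtarget.phantom import PhantomSpec, generate_series
from gdmtarget.registration import run_study


@pytest.fixture(scope="session")
def phantom():
    """One default phantom study (seed 1), rendered once per session."""
    spec = PhantomSpec(seed=1)
    study, truth = generate_series(spec)
    return spec, study, truth


@pytest.fixture(scope="session")
def phantom_chains(phantom):
    """The triple-registration chains for every secondary of the session phantom."""
    _, study, _ = phantom
    return run_study(study)


@pytest.fixture
def unit_grid():
    return Grid((24, 24, 24), (1.0, 1.0, 1.0))


@pytest.fixture
def cube(unit_grid):
    """10 mm cube centred in a 24³ unit grid."""
    m = np.zeros(unit_grid.shape, dtype=bool)
    m[7:17, 7:17, 7:17] = True
    return BinaryStructure(m, unit_grid, "cube")
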