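import numpy as np
import pytest

from tetrd import bind_model, compute_measures, generate_box
from tetrd.fixtures import two_tet_mesh, two_tet_toy_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unit_box():
    """1 µm³ box, one cell -> 6 tets, 12 boundary triangles."""
    return generate_box((1e-6, 1e-6, 1e-6), (1, 1, 1))


@pytest.fixture
def two_tets():
    return two_tet_mesh()


@pytest.fixture
def toy_bound():
    model, mesh = two_tet_toy_fixture()
    return bind_model(model, mesh)


@pytest.fixture
def toy_bound_no_ghk():
    model, mesh = two_tet_toy_fixture(ghk_on=False)
    return bind_model(model, mesh)


@pytest.fixture
def box_measures(unit_box):
    return compute_measures(unit_box)
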