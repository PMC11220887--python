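import numpy as np
import pytest

from sadret import SpaceGroupOps, SyntheticSpec, UnitCell, make_dataset, normalize_to_E


@pytest.fixture(scope="session")
def p1():
    return SpaceGroupOps.from_symbol("P1")


@pytest.fixture(scope="session")
def p1bar():
    return SpaceGroupOps.from_symbol("P-1")


@pytest.fixture(scope="session")
def p21():
    return SpaceGroupOps.from_strings(["x,y,z", "-x,y+1/2,-z"])


@pytest.fixture(scope="session")
def p212121():
    return SpaceGroupOps.from_symbol("P212121")


@pytest.fixture(scope="session")
def ortho_cell():
    return UnitCell(30.0, 34.0, 38.0)


@pytest.fixture(scope="session")
def small_p1_problem(p1):
    """Noise-free 5-atom P1 dataset, prepped to E values (fast fixture)."""
    cell = UnitCell(24.0, 26.0, 28.0)
    spec = SyntheticSpec(cell=cell, sg=p1, n_atoms=5, d_min=2.2, seed=101)
    refl, truth = make_dataset(spec, "direct_fa")
    refl = normalize_to_E(refl, sg=p1)
    return cell, p1, refl, truth


@pytest.fixture(scope="session")
def small_p212121_problem(p212121):
    """Noise-free 4-atom P212121 dataset, prepped to E values."""
    cell = UnitCell(26.0, 30.0, 34.0)
    spec = SyntheticSpec(cell=cell, sg=p212121, n_atoms=4, d_min=2.3, seed=7)
    refl, truth = make_dataset(spec, "direct_fa")
    refl = normalize_to_E(refl, sg=p212121)
    return cell, p212121, refl, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
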