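import numpy as np
import pytest

from nanoxtal.symmetry import UnitCell
from nanoxtal.sim_crystal import generate_pseudo_structure, structure_factors


@pytest.fixture(scope="session")
def ortho_cell():
    """The orthorhombic peptide-crystal cell used throughout."""
    return UnitCell(16.2, 29.1, 47.7)


@pytest.fixture(scope="session")
def p212121_model(ortho_cell):
    return generate_pseudo_structure(7, 6, ortho_cell, "P212121")


@pytest.fixture(scope="session")
def p212121_reference(p212121_model):
    """Complete Friedel-unique structure factors to 3.3 A."""
    return structure_factors(p212121_model, 3.3)


@pytest.fixture(scope="session")
def p1_model():
    cell = UnitCell(10.3, 11.7, 12.4)
    return generate_pseudo_structure(3, 3, cell, "P1")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
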