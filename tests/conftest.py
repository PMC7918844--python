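import numpy as np
import pytest

from dhdl import CellGeometry, ElectrolyteInterface, SeriesControl


@pytest.fixture
def water_like():
    """Electrolyte with lD = 1 and symmetric dielectrics (eps_l = eps_w)."""
    return ElectrolyteInterface(lD=1.0, eps_ratio=1.0)


@pytest.fixture
def unit_cell_disk():
    """Disk of radius 0.4 R in a unit cell."""
    return CellGeometry(R=1.0, r0=0.4)


@pytest.fixture
def fixed_ctrl():
    return SeriesControl(n_max=2000, adaptive=False)


@pytest.fixture
def radial_grid():
    return np.linspace(0.0, 1.0, 101)
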