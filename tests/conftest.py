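import numpy as np
import pytest

from crowdcell.geometry import CellGeometry, generate_geometry


@pytest.fixture(scope="session")
def empty_cell():
    return CellGeometry(1.0)


@pytest.fixture(scope="session")
def small_crowded():
    """A small random obstacle world (fast to query, non-trivial)."""
    return generate_geometry(cell_radius=0.8, n_cylinders=60, cyl_length=0.6,
                             cyl_radius=0.02, n_spheres=200, sph_radius=0.03,
                             seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
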