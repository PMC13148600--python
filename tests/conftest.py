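import matplotlib
matplotlib.use("Agg")

import numpy as np
import pytest

from holofield import DepthGrid, GridSpec, render_phantom, simulate_hologram, \
    three_disc_phantom, three_glyph_phantom


@pytest.fixture(scope="session")
def grid128():
    """Reference-scale synthetic grid: 128 px, 10 nm pixels, 0.1327 nm."""
    return GridSpec(128, 128, 10e-9, 10e-9, 0.1327e-9)


@pytest.fixture(scope="session")
def depth81():
    """Reference-scale depth stack: z' = 100 um, dz = 20 nm, 81 slices."""
    return DepthGrid(100e-6, 20e-9, 81)


@pytest.fixture(scope="session")
def glyph_reference(grid128):
    """Rendered default glyph phantom: (phase, absorbance, regions)."""
    return render_phantom(three_glyph_phantom(grid128))


@pytest.fixture(scope="session")
def glyph_hologram(grid128, glyph_reference):
    phase, absorb, _ = glyph_reference
    return simulate_hologram(phase, absorb, 100e-6, grid128)


@pytest.fixture(scope="session")
def small_grid():
    """Desk-scale grid for training tests: 48 px, 20 nm pixels."""
    return GridSpec(48, 48, 20e-9, 20e-9, 0.1327e-9)


@pytest.fixture(scope="session")
def small_depth():
    return DepthGrid(100e-6, 20e-9, 13)


@pytest.fixture(scope="session")
def small_reference(small_grid):
    return render_phantom(three_disc_phantom(small_grid))


@pytest.fixture(scope="session")
def small_hologram(small_grid, small_reference):
    phase, absorb, _ = small_reference
    return simulate_hologram(phase, absorb, 100e-6, small_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
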