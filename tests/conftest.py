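import numpy as np
import pytest

from leafspec import (
    SimulationConfig,
    build_wavelength_grid,
    generate_bundle,
    instrument_grid,
)
from leafspec.grids import CubeGeometry


@pytest.fixture(scope="session")
def grid243():
    return instrument_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20231105)


@pytest.fixture(scope="session")
def small_grid():
    return build_wavelength_grid(550.0, 1700.0, 24)


@pytest.fixture(scope="session")
def mini_bundle():
    """CI-scale simulated bundle: 8 plants, 16x16x24 cubes."""
    config = SimulationConfig.mini()
    chem, scenes = generate_bundle(config, seed=42)
    return config, chem, scenes


@pytest.fixture(scope="session")
def default_bundle():
    """Full study-structured bundle: 120 plants at reduced cube size."""
    chem, scenes = generate_bundle(SimulationConfig(), seed=11)
    return chem, scenes


def make_geometry(n_lines, n_samples, pixel_mm=5.0):
    return CubeGeometry(n_lines, n_samples, pixel_mm)
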