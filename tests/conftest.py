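import numpy as np
import pytest

from flowdht import (
    FlowSpec,
    OpticalConfig,
    PhantomSpec,
    Tomogram,
    generate_phantom,
)


@pytest.fixture(scope="session")
def optics() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom: 8 um cell on a 48^3 grid at 0.2 um voxels."""
    return PhantomSpec(grid_size=48, voxel_size=0.2, cell_radius=4.0,
                       correlation_length=0.8, seed=2, edge_voxels=2)


@pytest.fixture(scope="session")
def small_phantom(small_spec) -> Tomogram:
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def smooth_phantom() -> Tomogram:
    """Phantom at the system's native 0.1 um pixel with a resolution-scale edge."""
    spec = PhantomSpec(grid_size=96, voxel_size=0.1, cell_radius=4.0,
                       correlation_length=0.8, seed=2, edge_voxels=4)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def uniform_sphere() -> Tomogram:
    """Hard-edged uniform sphere, n = 1.354 in n0 = 1.334 (Delta-n = 0.02)."""
    spec = PhantomSpec(grid_size=96, voxel_size=0.1, cell_radius=4.0,
                       ri_range=(1.354, 1.354), correlation_length=0.5,
                       seed=0, edge_voxels=0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisefree_flow() -> FlowSpec:
    return FlowSpec(noise_sigma=0.0, n_frames=40, seed=5)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
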