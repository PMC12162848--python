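import numpy as np
import pytest

from dpsf import (
    BitDepthPolicy,
    DiffractiveProcessor,
    Dispersion,
    ProcessorGeometry,
    TrainConfig,
    random_uniform_target,
    train,
)


@pytest.fixture(scope="session")
def material():
    return Dispersion.constant(1.6518)


@pytest.fixture
def tiny_geometry():
    """K=2 surfaces, 6x6 features each, one 2x2 plane in and out."""
    return ProcessorGeometry.from_feature_count(
        n_features=2 * 36,
        n_surfaces=2,
        wavelength=1.0,
        input_shape=(1, 2, 2),
        output_shape=(1, 2, 2),
    )


@pytest.fixture
def tiny_processor(tiny_geometry, material):
    return DiffractiveProcessor.initialize(tiny_geometry, material, [1.0], seed=3)


def gaussian_field_samples(n: int, sigma_px: float = 2.5) -> np.ndarray:
    """Centred Gaussian amplitude: smooth, negligible evanescent content."""
    y, x = np.mgrid[:n, :n] - (n - 1) / 2.0
    return np.exp(-(x**2 + y**2) / (2 * sigma_px**2)).astype(np.complex128)


@pytest.fixture(scope="session")
def trained_small(material):
    """A small converged design on a random target, shared across tests.

    K=4 surfaces of 8x8 features (N = 256 = 4*N_i*N_o) realizing a seeded
    uniform-random target between two 2x2-voxel planes on each side.
    """
    geom = ProcessorGeometry.from_feature_count(
        n_features=256,
        n_surfaces=4,
        wavelength=1.0,
        input_shape=(2, 2, 2),
        output_shape=(2, 2, 2),
        d_i=3.5,
        d_o=3.5,
    )
    target = random_uniform_target(
        geom.n_output_voxels, geom.n_input_voxels, seed=7,
        input_shape=geom.input_shape, output_shape=geom.output_shape,
    )
    proc = DiffractiveProcessor.initialize(geom, material, [1.0], seed=11)
    config = TrainConfig(iterations=300, seed=11, policy=BitDepthPolicy())
    result = train(proc, target, config)
    return {"result": result, "target": target, "geometry": geom}
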