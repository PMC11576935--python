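import numpy as np
import pytest

from discus import (
    NetworkConfig,
    DiscusNet,
    build_shell_scheme,
    TensorCompartment,
    VoxelGroundTruth,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_shell_scheme():
    """90 directions at b=1000 plus 3 b0 volumes."""
    return build_shell_scheme([90], [1000.0], seed=7, n_b0=3)


@pytest.fixture(scope="session")
def small_scheme():
    """30 directions at b=1000 plus one b0 — cheap fits."""
    return build_shell_scheme([30], [1000.0], seed=3, n_b0=1)


@pytest.fixture(scope="session")
def default_net():
    """Untrained default-architecture network (invariances hold for any weights)."""
    return DiscusNet(NetworkConfig(), seed=0)


@pytest.fixture
def tiny_config():
    """Small widths: fast forward/backward, float64-friendly for grad checks."""
    return NetworkConfig(
        width=8,
        latent_dim=3,
        si_hidden_layers=1,
        transform_hidden_layers=1,
        decoder_hidden_layers=1,
        encoder_stages=2,
    )


@pytest.fixture
def single_fiber_voxel():
    return VoxelGroundTruth(
        [
            TensorCompartment(
                np.array([1.7e-3, 0.3e-3, 0.3e-3]), np.array([0.3, 0.5, 0.9]), 1.0
            )
        ]
    )


@pytest.fixture
def isotropic_voxel():
    return VoxelGroundTruth(
        [TensorCompartment(np.array([0.7e-3, 0.7e-3, 0.7e-3]), np.array([0.0, 0.0, 1.0]), 1.0)]
    )
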