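import numpy as np
import pytest

from pcctdenoise.containers import SpectralVolume
from pcctdenoise.phantom_sim import (
    NoiseSpec,
    add_noise,
    build_sensitivity_matrix,
    compose_phantom,
    random_phantom_spec,
)


@pytest.fixture(scope="session")
def sensitivity():
    """Default 4-material x 4-energy K-edge sensitivity matrix."""
    M = build_sensitivity_matrix()
    M.vial_concentrations = {
        "water": 1.0, "iodine": 10.0, "gadolinium": 10.0, "calcium": 10.0,
    }
    return M


@pytest.fixture(scope="session")
def small_phantom(sensitivity):
    """Small vial phantom: (ground-truth maps, clean volume)."""
    spec = random_phantom_spec(seed=7, grid_shape=(12, 32, 32))
    return compose_phantom(spec, sensitivity)


@pytest.fixture(scope="session")
def noisy_pair(small_phantom):
    """(clean, noisy) float32 pair at the default noise levels."""
    _, clean = small_phantom
    clean32 = SpectralVolume(
        clean.data.astype(np.float32), clean.energies, clean.voxel_size_mm
    )
    return clean32, add_noise(clean32, NoiseSpec(seed=11))
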