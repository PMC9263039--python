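import numpy as np
import pytest

from holoassay.config import OpticsConfig


@pytest.fixture(scope="session")
def optics_small() -> OpticsConfig:
    """Coarse sensor grid (same physical FOV) for fast end-to-end tests."""
    return OpticsConfig(sensor_cols=256, sensor_rows=192)


@pytest.fixture(scope="session")
def optics_quiet() -> OpticsConfig:
    """Noise-free small-grid optics for deterministic oracle checks."""
    return OpticsConfig(
        sensor_cols=256,
        sensor_rows=192,
        shot_noise_scale=0.0,
        parasitic_fringe_amplitude=0.0,
        background_aberration_rad=0.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
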