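import numpy as np
import pytest

from nervelight.media import NerveModel, OpticalMedium
from nervelight.transport import RunConfig


@pytest.fixture
def white_matter():
    return OpticalMedium(mu_s=43.0, mu_a=0.35, g=0.8, n=1.32)


@pytest.fixture
def nerve(white_matter):
    """Canonical 1 mm diameter nerve analog in air."""
    return NerveModel(radius=0.5, length=2.0, medium=white_matter,
                      external_n=1.0)


@pytest.fixture
def tiny_config():
    """Small deterministic run configuration for fast tests."""
    return RunConfig(seed=123, rays_per_point=5, deposition_step=1e-3,
                     voxel_size=1e-2)


@pytest.fixture
def rng():
    return np.random.RandomState(20260922)
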