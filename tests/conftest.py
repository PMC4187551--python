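import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungadc import ImageVolume, LungMask, PhantomSpec, generate_lung_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Small acquisition geometry used throughout: 7 coronal slices of 30 mm
#: pitch, 64 x 64 in-plane. Big enough for two lungs and SI thirds, small
#: enough to keep simulations fast.
SMALL_SHAPE = (7, 64, 64)
SMALL_SPACING = (30.0, 6.25, 6.25)


@pytest.fixture
def flat_spec() -> PhantomSpec:
    """Noiseless phantom with a spatially uniform ADC field."""
    return PhantomSpec(shape=SMALL_SHAPE, spacing=SMALL_SPACING,
                       baseline_adc=0.23, seed=0)


@pytest.fixture
def flat_phantom(flat_spec):
    return generate_lung_phantom(flat_spec)


@pytest.fixture
def two_population_image() -> tuple[ImageVolume, np.ndarray]:
    """Background N(5, 5) / signal N(100, 5) image with a known signal mask."""
    rng = np.random.default_rng(42)
    signal = np.zeros(SMALL_SHAPE, dtype=bool)
    signal[:, 16:48, 8:28] = True
    signal[:, 16:48, 36:56] = True
    data = rng.normal(5.0, 5.0, SMALL_SHAPE)
    data[signal] = rng.normal(100.0, 5.0, int(signal.sum()))
    return ImageVolume(data, SMALL_SPACING), signal


@pytest.fixture
def square_mask_volume() -> tuple[ImageVolume, LungMask]:
    """Single-slice flat-signal volume with Gaussian background noise."""
    rng = np.random.default_rng(7)
    data = rng.normal(0.0, 5.0, (1, 64, 64))
    mask = np.zeros((1, 64, 64), dtype=bool)
    mask[0, 20:44, 20:44] = True
    data[mask] += 100.0
    return ImageVolume(data, (30.0, 6.25, 6.25)), LungMask(mask, (30.0, 6.25, 6.25))
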