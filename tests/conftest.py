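import numpy as np
import pytest

from fiberaniso import FiberSimConfig, IntensityImage, simulate_fiber_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Small strictly-positive random field."""
    return IntensityImage(rng.uniform(0.0, 255.0, (64, 64)), pixel_size_um=1.0)


@pytest.fixture
def step_edge():
    """Vertical step: left half 0, right half 1."""
    px = np.zeros((64, 64))
    px[:, 32:] = 1.0
    return IntensityImage(px, pixel_size_um=1.0)


def small_sim_config(**kw):
    """Quarter-size frame at the standard pixel pitch (for fast tests)."""
    kw.setdefault("image_px", 256)
    kw.setdefault("fov_um", 90.0)
    kw.setdefault("n_fibers", 20)
    return FiberSimConfig(**kw)


@pytest.fixture
def aligned_image():
    return simulate_fiber_image(
        small_sim_config(angle_range_deg=(85, 95), diameter_um=4, seed=7))


@pytest.fixture
def unaligned_image():
    return simulate_fiber_image(
        small_sim_config(angle_range_deg=(0, 180), diameter_um=4, seed=7))
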