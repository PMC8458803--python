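import numpy as np
import pytest

from natsc import (
    build_phantom,
    default_echo_schedule,
    default_phantom_spec,
    simulate_multiecho,
)


@pytest.fixture(scope="session")
def schedule():
    return default_echo_schedule()


@pytest.fixture(scope="session")
def small_phantom():
    """Default geometry on a 24-voxel grid (fast to render and fit)."""
    return build_phantom(default_phantom_spec(grid_size=24))


@pytest.fixture(scope="session")
def noiseless_image(small_phantom, schedule):
    return simulate_multiecho(small_phantom, schedule, noise_sd=0.0, blur_fwhm=0.0)
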