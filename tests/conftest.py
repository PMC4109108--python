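import numpy as np
import pytest

from rsdfseg import InitialContourSpec, render_phantom, two_level_disc


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_image(rng):
    """Random 8x8 intensity field on [0, 255]."""
    return rng.uniform(0.0, 255.0, (8, 8))


@pytest.fixture
def small_phi(rng):
    """Random level-set field on the same 8x8 grid."""
    return rng.uniform(-3.0, 3.0, (8, 8))


@pytest.fixture(scope="session")
def disc_phantom():
    """Clean two-level disc phantom (values {51, 153}) with truth mask."""
    return render_phantom(two_level_disc())


@pytest.fixture(scope="session")
def disc_init():
    """Rectangle straddling the disc boundary (disc: centre 64, radius 32)."""
    return InitialContourSpec("rectangle", (32, 32, 96, 96))
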