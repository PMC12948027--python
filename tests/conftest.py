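import numpy as np
import pytest

from xrfres import ElementalMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_map(rng):
    """A small background-subtracted-looking map: mostly noise about zero
    with a smooth positive structure, anisotropic pitch."""
    ny, nx = 32, 48
    yy, xx = np.mgrid[0:ny, 0:nx]
    structure = 5.0 * np.exp(-((xx - 20) ** 2 + (yy - 16) ** 2) / 50.0)
    noise = 0.3 * rng.standard_normal((ny, nx))
    return ElementalMap(values=structure + noise, dx=1.0, dy=2.0,
                        element="Ca", dwell=0.05)
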