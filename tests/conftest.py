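import numpy as np
import pytest

from micromorph import morphometry as mm
from micromorph import simgen as sg


@pytest.fixture(scope="session")
def disk_mask():
    """Rasterized disk, r = 50 px."""
    yy, xx = np.mgrid[:120, :120]
    return (yy - 60) ** 2 + (xx - 60) ** 2 <= 50**2


@pytest.fixture(scope="session")
def square_mask():
    """100 x 100 px square."""
    m = np.zeros((120, 120), dtype=bool)
    m[10:110, 10:110] = True
    return m


@pytest.fixture(scope="session")
def cross_mask():
    """Cross of two 100 x 20 px bars (area 3600, hull 6800)."""
    m = np.zeros((140, 140), dtype=bool)
    m[60:80, 20:120] = True
    m[20:120, 60:80] = True
    return m


@pytest.fixture(scope="session")
def ellipse_mask():
    """Ellipse with semi-axes 60 / 20 px."""
    yy, xx = np.mgrid[:300, :300]
    return ((yy - 150) / 20.0) ** 2 + ((xx - 150) / 60.0) ** 2 <= 1.0


def render_random_cells(n, seed, class_probs=(0.5, 0.25, 0.25)):
    """Render n cells with class-conditional default parameters.

    Yields (true_morphotype, mask) pairs; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        morph = str(
            rng.choice(np.array(mm.MORPHOTYPES, dtype=object), p=class_probs)
        )
        params = sg.sample_shape_params(morph, rng)
        mask, _ = sg.generate_cell_shape(params, int(rng.integers(0, 2**31 - 1)))
        out.append((morph, mask))
    return out
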