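import numpy as np
import pytest

import fpmkit as fk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bar_mask():
    """Horizontal bar, 40 px long, 4 px wide."""
    mask = np.zeros((20, 60), dtype=bool)
    mask[8:12, 10:50] = True
    return mask


@pytest.fixture
def disk_mask():
    mask = np.zeros((40, 40), dtype=bool)
    rr, cc = np.mgrid[0:40, 0:40]
    mask[(rr - 20) ** 2 + (cc - 20) ** 2 <= 100] = True
    return mask


@pytest.fixture(scope="session")
def sshape_scene():
    """Noiseless S-ribbon with dipoles normal to the generating curve."""
    return fk.make_sshape_scene(dipole="normal")


@pytest.fixture(scope="session")
def puncta_scene():
    """Noiseless 30-punctum field with known order/azimuth."""
    return fk.make_puncta_field(n=30, seed=7)


def forward_pixel(amplitude, p, alpha_deg, background=0.0):
    """Independent evaluation of the polarization response at 0/45/90/135."""
    omega = np.deg2rad([0.0, 45.0, 90.0, 135.0])
    alpha = np.deg2rad(alpha_deg)
    return background + amplitude * (1.0 + p * np.cos(2.0 * (omega - alpha))) / 2.0
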