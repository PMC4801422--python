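import math

import numpy as np
import pytest
from hypothesis import settings

from nmjmorph.io_stack import Calibration

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def cal_unit() -> Calibration:
    """1 px/um calibration so pixel counts read directly as um."""
    return Calibration(px_per_um_xy=1.0, z_step_um=0.3, n_planes=10)


@pytest.fixture
def cal_widefield() -> Calibration:
    return Calibration()  # 6.932 px/um, 0.3 um z-step, 42 planes


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def disc_chain(k, radius=12, spacing_factor=1.6):
    """k overlapping discs in a row, centers spacing_factor*radius apart."""
    sp = spacing_factor * radius
    h = int(4 * radius)
    w = int(k * sp + 4 * radius)
    m = np.zeros((h, w), dtype=bool)
    for i in range(k):
        m |= disc_mask((h, w), (h / 2, 2 * radius + i * sp), radius)
    return m


def raster_y(shape=(80, 80), center=(40, 40), arms=(90, 210, 330), length=30):
    """Three thin arms from one center, as a raw pixel set."""
    m = np.zeros(shape, dtype=bool)
    for ang in arms:
        th = math.radians(ang)
        for t in np.linspace(0, length, 2 * length + 1):
            m[
                int(round(center[0] + t * math.sin(th))),
                int(round(center[1] + t * math.cos(th))),
            ] = True
    return m
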