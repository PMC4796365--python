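"""Shared fixtures: small geometries and fast synthetic configurations."""

import numpy as np
import pytest

from micropassage.microdevice import ChannelGeometry
from micropassage.synthgen import NoiseParams


@pytest.fixture
def geometry():
    """Small hand-checkable geometry: W=2, L=10, center 20, 0.5 um px."""
    return ChannelGeometry(
        channel_width_um=7.0, channel_height_um=5.0,
        constriction_width_um=2.0, constriction_length_um=10.0,
        constriction_center_x_um=20.0, pixel_size_um=0.5)


@pytest.fixture
def quiet_noise():
    """Noise-free camera for render-then-measure closure tests."""
    return NoiseParams(poisson=False, read_noise_sd=0.0)


def make_disk(radius_px: int, pad: int = 6, antialias: bool = True):
    """Rasterized disk; anti-aliased coverage unless ``antialias=False``."""
    n = 2 * (radius_px + pad) + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    dist = np.hypot(yy - c, xx - c)
    if antialias:
        return np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    return (dist <= radius_px).astype(float)
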