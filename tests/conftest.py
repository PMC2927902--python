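import numpy as np
import pytest

import widefieldct as w


@pytest.fixture(scope="session")
def paper_geometry():
    """Three 1024-px subscans with 100-px overlaps (covered width 2872)."""
    return w.plan_widefield(2872, 1024, 100, pixel_size_um=1.48)


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-scale three-subscan layout: D=144, overlaps 24, covered 384."""
    return w.plan_widefield(384, 144, 24, pixel_size_um=1.48)


@pytest.fixture(scope="session")
def small_phantom():
    return w.shepp_logan(384)


@pytest.fixture(scope="session")
def small_subscans(small_geometry, small_phantom):
    """Noiseless subscans of the 384-px phantom at 24 equal angles."""
    angles = np.arange(24) * (180.0 / 24)
    return [
        w.forward_project(small_phantom, angles, off, 144)
        for off in small_geometry.offsets_px
    ]


@pytest.fixture(scope="session")
def small_wide(small_phantom):
    angles = np.arange(24) * (180.0 / 24)
    return w.wide_projection(small_phantom, angles)
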