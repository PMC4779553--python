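import numpy as np
import pytest

from marquant import PhantomSpec, generate_case
from marquant.geometry import SliceContours, VoxelGrid


def circle(cx, cy, r, n=72):
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


@pytest.fixture(scope="session")
def annulus_grid():
    return VoxelGrid(rows=128, cols=128, n_slices=1, in_plane_spacing=1.5)


@pytest.fixture(scope="session")
def annulus_contours(annulus_grid):
    """One-slice annulus: epicardial r=30 mm, endocardial r=20 mm."""
    c = (annulus_grid.cols - 1) / 2 * annulus_grid.in_plane_spacing
    return {"ED": {0: SliceContours(endo=circle(c, c, 20.0), epi=circle(c, c, 30.0))}}


@pytest.fixture(scope="session")
def default_case():
    """The default phantom: 90 deg MaR wedge, contrast 1.3, 5 % noise, bias, MVO."""
    return generate_case(PhantomSpec())


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free, bias-free phantom without MVO (exact generative intensities)."""
    return generate_case(PhantomSpec(noise_sd=0.0, coil_bias=False, mvo=False))
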