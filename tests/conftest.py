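import numpy as np
import pytest

import leafsurf as ls


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_rectangle():
    """Dense flat rectangle grid, base at the origin, extending along +x."""
    x, y = np.meshgrid(np.linspace(0, 80, 161), np.linspace(-15, 15, 61))
    coords = np.stack([x.ravel(), y.ravel(), np.zeros(x.size)], axis=1)
    return ls.PointCloud3(coords)


@pytest.fixture
def bent_leaf():
    """Noiseless synthetic leaf with bending and rolling distortion."""
    spec = ls.SyntheticLeafSpec(
        length=100, max_width=40, density=3, bend_sag=20, roll_amplitude=8, seed=1
    )
    return ls.generate_leaf(spec)


@pytest.fixture
def leaf_frame_cloud(bent_leaf):
    return bent_leaf.leaf_truth
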