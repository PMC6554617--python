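import numpy as np
import pytest

from shapeappear import (
    Deformation,
    GridSpec,
    VelRegWeights,
    build_velocity_operator,
)
from shapeappear.diffeo import identity_map


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid8():
    return GridSpec((8, 8))


@pytest.fixture
def grid6():
    return GridSpec((6, 6))


def smooth_field(grid, rng, n_comp=None, scale=1.0, weights=(1e-2, 0, 2.0, 0.5, 0.5)):
    """Green's-smoothed random field, rescaled to unit peak times `scale`."""
    op = build_velocity_operator(grid, VelRegWeights(*weights))
    shape = grid.dims + (grid.ndim,)
    w = op.apply_inverse(rng.standard_normal(shape))
    w *= scale / np.abs(w).max()
    if n_comp == 1:
        return w[..., 0]
    return w


def random_deformation(grid, rng, scale=0.8):
    """A smooth non-identity deformation for resampling tests."""
    disp = smooth_field(grid, rng, scale=scale)
    return Deformation(grid, identity_map(grid) + disp)


@pytest.fixture
def smooth_deformation(grid8, rng):
    return random_deformation(grid8, rng)
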