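import numpy as np
import pytest

from oncotoc.fields import (
    GaussianFieldModel,
    Grid,
    LumpyFieldModel,
    ScalarField,
    TemporalField,
)


@pytest.fixture
def grid3d() -> Grid:
    return Grid((8, 8, 8), (1.0, 1.0, 1.0))


@pytest.fixture
def grid2d() -> Grid:
    """Single-slice grid used for fast imaging tests."""
    return Grid((8, 8, 1), (1.0, 1.0, 1.0))


@pytest.fixture
def grid1d() -> Grid:
    return Grid((64, 1, 1), (0.25, 1.0, 1.0))


@pytest.fixture
def gauss_model() -> GaussianFieldModel:
    return GaussianFieldModel(mean=1.0, sigma2=0.25, corr_length=2.0)


@pytest.fixture
def lumpy_model() -> LumpyFieldModel:
    return LumpyFieldModel(kbar=10.0, amplitude=0.5, width=1.5, offset=0.2)


@pytest.fixture
def smooth_bump(grid3d) -> ScalarField:
    return ScalarField.from_function(
        grid3d,
        lambda x, y, z: np.exp(-((x - 4) ** 2 + (y - 4) ** 2 + (z - 4) ** 2) / 8.0),
    )


def make_temporal(grid, n_t=4, dt=0.5, value=1.0):
    times = dt * np.arange(n_t)
    return TemporalField.constant(grid, times, value, nonnegative=value >= 0)
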