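import numpy as np
import pytest

from sparse_xanes import (
    default_standards_library,
    make_energy_grid,
)
from sparse_xanes.background_augmentation import default_background_config
from sparse_xanes.reduced_basis import compute_basis

FE_EDGE = 7112.0


@pytest.fixture(scope="session")
def fe_grid():
    return make_energy_grid(FE_EDGE)


@pytest.fixture(scope="session")
def standards13(fe_grid):
    """12 randomized Fe-like standards plus the flat 1e-8 column."""
    return default_standards_library(seed=0, grid=fe_grid)


@pytest.fixture(scope="session")
def standards4(fe_grid):
    """A small 4-standard library (no flat column) for noisy fixtures."""
    return default_standards_library(n_standards=4, seed=3, grid=fe_grid,
                                     add_flat=False)


@pytest.fixture(scope="session")
def bg_cfg_full(fe_grid):
    return default_background_config(fe_grid, FE_EDGE, n_variants=50, seed=5)


@pytest.fixture(scope="session")
def basis13(standards13):
    return compute_basis(standards13)


def random_orthonormal(m, k, seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((m, k)))
    return q
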