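import logging

import numpy as np
import pytest

from eemviva.grid import build_acquisition_grid
from eemviva.parafac import canonicalize, fit_parafac
from eemviva.preprocess import preprocess_cube
from eemviva.synthetic import generate_cube

logging.getLogger("eemviva").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def paper_grid():
    return build_acquisition_grid()


@pytest.fixture(scope="session")
def default_cube():
    """Default synthetic study cube (seed 7) with its ground truth."""
    return generate_cube(seed=7)


@pytest.fixture(scope="session")
def preprocessed_cube(default_cube):
    cube, _ = default_cube
    return preprocess_cube(cube)


@pytest.fixture(scope="session")
def fitted_five(preprocessed_cube):
    """Five-component multi-start fit of the default cube (full settings)."""
    return fit_parafac(preprocessed_cube, 5, n_starts=10, seed=7)


def random_nonneg_factors(I, J, K, F, seed):
    """Seeded random non-negative factor matrices in canonical form."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.5, 2.0, (I, F))
    B = rng.uniform(0.1, 1.0, (J, F))
    C = rng.uniform(0.1, 1.0, (K, F))
    return canonicalize(A, B, C)


def exact_tensor(A, B, C):
    return np.einsum("if,jf,kf->ijk", A, B, C)
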