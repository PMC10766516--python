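"""Shared fixtures: grids, Gaussian species, synthetic pools and databases.

Everything is generated programmatically at session scope so the expensive
pieces (the 90-species pool) are built once.
"""

import numpy as np
import pytest

from cf22d.grids import build_grid
from cf22d.density import GaussianShellSpec, gaussian_ingredients
from cf22d.xc.params import default_ingredient_constants
from cf22d.synthetic import (
    SyntheticSpec,
    make_species_pool,
    make_database,
    random_parameters,
    default_dispersion_params,
)


@pytest.fixture(scope="session")
def funcs():
    return default_ingredient_constants()


@pytest.fixture(scope="session")
def one_gaussian():
    """Closed-shell single s-Gaussian (2 electrons) on its default grid."""
    shell = GaussianShellSpec((0.0, 0.0, 0.0), 1.3, (1.0, 1.0))
    grid = build_grid([[0.0, 0.0, 0.0]], radial_count=60, angular_count=50)
    return shell, grid, gaussian_ingredients([shell], grid)


@pytest.fixture(scope="session")
def species_pool():
    spec = SyntheticSpec(seed=1)
    return spec, make_species_pool(spec)


@pytest.fixture(scope="session")
def planted_params():
    return random_parameters(np.random.default_rng(7))


@pytest.fixture(scope="session")
def dispersion_params():
    return default_dispersion_params(1.53)


@pytest.fixture(scope="session")
def noiseless_database(species_pool, planted_params, dispersion_params):
    spec, pool = species_pool
    return make_database(spec, pool, planted_params, sr6=1.53, dispersion=dispersion_params)
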