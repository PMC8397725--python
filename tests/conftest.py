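import numpy as np
import pytest

from tpdiv.space import fit_space
from tpdiv.synthetic import SyntheticConfig, gen_trait_table
from tpdiv.tpd import GridSpec, KernelConfig, bandwidth_matrix, build_grid, species_cell_masses


@pytest.fixture(scope="session")
def small_world():
    """A fixed synthetic world with its fitted space, grid, kernel and cached masses."""
    cfg = SyntheticConfig(n_species=120, n_traits=5, seed=42)
    traits = gen_trait_table(cfg)
    space = fit_space(traits, D=2)
    coords = space.coords.to_numpy()
    grid = build_grid(coords, 60)
    kernel = bandwidth_matrix(coords)
    masses = species_cell_masses(coords, kernel, grid)
    return {
        "cfg": cfg,
        "traits": traits,
        "space": space,
        "coords": coords,
        "grid": grid,
        "kernel": kernel,
        "masses": masses,
    }


@pytest.fixture
def unit_kernel():
    return KernelConfig(H=np.eye(2), selector="normal_reference")


@pytest.fixture
def square_grid():
    return GridSpec((-6.0, -6.0), (6.0, 6.0), (120, 120))
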