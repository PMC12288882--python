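import numpy as np
import pytest

from declust.simulation import make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """10×10 lattice, 4 quadrant domains, 30 cells/type — fast shared fixture."""
    sc_ref, sim, domains = make_fixture(
        n_spots=100, n_genes=80, k=4, n_cells_per_type=30,
        markers_per_type=10, effect_size=4.0, rng_seed=11,
    )
    return sc_ref, sim, domains


@pytest.fixture
def rng():
    return np.random.default_rng(0)
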