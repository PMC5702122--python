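import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stokesbd as sb

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_domain():
    return sb.DomainSpec(200, 100)


@pytest.fixture(scope="session")
def packed_cells(small_domain):
    return sb.pack_cells(small_domain, 10.0, 0.40, rng_seed=2)


@pytest.fixture(scope="session")
def solved_system(small_domain, packed_cells):
    disc = sb.discretize_boundaries(small_domain, packed_cells, 1000, 1.0)
    return sb.solve_forces(disc)


@pytest.fixture(scope="session")
def no_cells():
    return sb.CellField(np.empty((0, 2)), 10.0, 0.0)


@pytest.fixture(scope="session")
def tissue():
    """Packed 400x200 um tissue at 40% cell area with its base config."""
    from stokesbd.cli import make_fixture

    return make_fixture("small_tissue", seed=5)


@pytest.fixture(scope="session")
def single_cell_capture_run():
    """Ensemble in a closed 30x30 box around one cell, rho=0.2: every particle
    is eventually captured, so contact counts sample the geometric law."""
    cells = sb.CellField(np.array([[15.0, 15.0]]), 10.0, np.pi * 100 / 900)
    cfg = sb.RunConfig(
        domain_width=30, domain_height=30, porosity=1.0, v_in=0.0,
        n_particles=400, t_end=200.0, seed=7, capture_probability=0.2,
    )
    entry = np.column_stack([np.full(400, 2.0), np.full(400, 15.0)])
    return sb.simulate_ensemble(cfg, cells=cells, entry_positions=entry)
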