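import numpy as np
import pytest

from cleftforce import Selection, fixtures
from cleftforce.efield import IonicMedium


@pytest.fixture
def chain_a():
    return Selection("A", chain="A")


@pytest.fixture
def chain_b():
    return Selection("B", chain="B")


@pytest.fixture
def saltfree_medium():
    """Aqueous medium with no electrolyte (κ = 0)."""
    return IonicMedium(ionic_strength_mM=0.0)


@pytest.fixture
def homogeneous_medium():
    """Uniform ε = 80, no salt: the Coulomb oracle regime for the PB solver."""
    return IonicMedium(solvent_dielectric=80.0, solute_dielectric=80.0,
                      ionic_strength_mM=0.0)


@pytest.fixture
def two_domain_traj():
    return fixtures.make_two_domain_trajectory(
        n_frames=1000, frame_interval_ns=0.1, mean_distance=10.0, sd=0.5,
        seed=7)


@pytest.fixture
def occupancy_traj_166():
    mask = np.zeros(1000, dtype=bool)
    mask[:166] = True
    return fixtures.make_occupancy_trajectory(mask)
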