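import numpy as np
import pytest

from dldroute.binning import BinGrid, SizeHistogram
from dldroute.simulate import SimulationConfig, simulate_experiment


@pytest.fixture
def unit_grid():
    """Ten unit-width bins on [0, 10]."""
    return BinGrid(edges=np.arange(11, dtype=float), width=1.0)


def make_hist(grid, counts, reservoir="small"):
    return SizeHistogram(grid=grid, counts=np.asarray(counts, dtype=float), reservoir=reservoir)


@pytest.fixture(scope="session")
def default_experiment():
    """One simulated experiment at the default study conditions."""
    return simulate_experiment(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_experiment():
    """A cheap experiment for plumbing tests."""
    return simulate_experiment(SimulationConfig(n_particles=800, seed=7))
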