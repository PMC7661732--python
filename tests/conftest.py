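import numpy as np
import pandas as pd
import pytest

from glycosync import AnalysisParams, PopulationSynchrony, SimulationConfig
from glycosync.simulate import Population


@pytest.fixture(scope="session")
def default_results():
    """Full fit of the packaged default simulation (one seed, reused)."""
    return PopulationSynchrony.from_simulation(SimulationConfig(seed=1)).fit()


@pytest.fixture(scope="session")
def sync_only_params():
    """Analysis params with the spatial cluster stage disabled (faster)."""
    return AnalysisParams(cluster_modes=())


def make_population(n_cells=5, n_samples=400, dt=2.0, f_mHz=20.0, seed=0):
    """Tiny synthetic population of clean sinusoids for unit tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * dt
    phases0 = rng.uniform(0, 2 * np.pi, n_cells)
    traces = 100.0 + np.sin(
        2 * np.pi * f_mHz * 1e-3 * t[None, :] + phases0[:, None]
    )
    xy = rng.uniform(-40, 40, size=(n_cells, 2))
    positions = pd.DataFrame(
        {"cell_id": np.arange(n_cells), "x_um": xy[:, 0], "y_um": xy[:, 1]}
    )
    return Population(t=t, traces=traces, positions=positions)


@pytest.fixture
def tiny_population():
    return make_population()
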