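import numpy as np
import pytest

from taintgen import ModelSpec, SimulationConfig, simulate
from taintgen.io import analysis_table


@pytest.fixture(scope="session")
def small_dataset():
    """60-animal, 4-trait dataset with complete records (shared, read-only)."""
    cfg = SimulationConfig(
        n_sires=8, n_progeny=60, dams_per_sire=8, n_grandsires=3,
        n_assessors=2, months_per_station=2, missing_assessors=(), seed=5)
    ds = simulate(cfg)
    table, _ = analysis_table(ds.phenotypes)
    model = ModelSpec(traits=["SKAt", "ANONt", "SENSt_1", "SENSt_2"])
    return ds, table, model


@pytest.fixture()
def random_pd_matrices():
    """Factory for random positive-definite symmetric matrices."""
    rng = np.random.default_rng(1234)

    def make(m: int, scale: float = 1.0):
        L = rng.standard_normal((m, m)) * scale
        return L @ L.T + 0.1 * scale ** 2 * np.eye(m)

    return make
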