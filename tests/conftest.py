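import numpy as np
import pytest

from sccsubtypes.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study: fast enough for unit tests, still well separated."""
    return SimulationConfig(
        k=3, n_per_cluster=10, n_genes=120, sig_size=12,
        n_mirs=60, mirs_up=3, mirs_down=3,
        n_compounds=12, n_cells_per_cluster=6, n_decoy_tfs=10,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
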