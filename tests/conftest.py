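import numpy as np
import pytest

from fretolig.proximity import ProximityConfig, simulate_proximity


@pytest.fixture(scope="session")
def prox_table():
    """Shared default-geometry proximity table (one MC run per session)."""
    return simulate_proximity(ProximityConfig(seed=123))


@pytest.fixture(scope="session")
def prox_table_small():
    """Cheap, coarser proximity table for tests that only need the shape."""
    return simulate_proximity(
        ProximityConfig(
            density_grid=np.linspace(0.0, 8000.0, 17),
            n_realizations=3000,
            seed=7,
        )
    )
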