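import numpy as np
import pandas as pd
import pytest

from osimc.phenotyping import default_ruleset
from osimc.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest multi-core cohort used by several stage tests."""
    cfg = CohortConfig(n_cores=10, cells_per_core=400, seed=11, ir191_pos_frac=0.9)
    return simulate_cohort(cfg)


def random_core(rng, n_cells, labels=("M2", "mMDSC", "pMDSC", "Treg", "Other"), size=1000.0):
    """A single random labeled core for spatial oracle tests."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "core_id": "core001",
            "x_um": rng.uniform(0, size, n_cells),
            "y_um": rng.uniform(0, size, n_cells),
            "phenotype": rng.choice(labels, n_cells),
        }
    )


@pytest.fixture
def make_core():
    return random_core
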