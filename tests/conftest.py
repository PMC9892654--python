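import numpy as np
import pytest

import boolmark as bm


@pytest.fixture(scope="session")
def sim_dataset():
    """A default-shape synthetic cohort (40 samples, 14/17/9) with strong signal."""
    ds = bm.simulate(bm.SimulationConfig(seed=11))
    matrix = bm.impute_missing(ds.matrix, seed=1)
    return ds, matrix


@pytest.fixture(scope="session")
def fast_plan():
    """A small shared holdout plan to keep classifier tests quick."""
    return bm.HoldoutPlan.from_seed(7, n_replicates=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
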