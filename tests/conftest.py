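import numpy as np
import pandas as pd
import pytest

import tauspread as ts


@pytest.fixture(scope="session")
def regions66():
    return ts.build_region_table("cortical66", coordinate_seed=0)


@pytest.fixture(scope="session")
def regions78():
    return ts.build_region_table("full78", coordinate_seed=0)


@pytest.fixture(scope="session")
def connectome(regions66):
    return ts.simulate_connectome(regions66, density=0.10, seed=1)


@pytest.fixture(scope="session")
def coarse_grid():
    return ts.ParameterGrid.coarse(n_rates=7, t_effs=(5, 10, 15, 20, 25, 30, 35, 40), dt=0.05)


@pytest.fixture(scope="session")
def benchmark_cohort(regions66, connectome):
    """Tau-accumulating cohort with observation noise, entorhinal epicenter."""
    return ts.simulate_cohort(
        regions66, connectome, ts.recovery_benchmark_spec(n=50), seed=7
    )


@pytest.fixture(scope="session")
def mixed_cohort(regions66, connectome):
    """Default-demographics cohort (CN/MCI/AD mix)."""
    return ts.simulate_cohort(regions66, connectome, ts.CohortSpec(n=120), seed=11)


def tiny_random_system(n_nodes: int, seed: int):
    """Small random symmetric weight matrix for oracle comparisons."""
    rng = np.random.default_rng(seed)
    w = rng.random((n_nodes, n_nodes))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    names = [f"n{i}" for i in range(n_nodes)]
    return ts.Connectome(pd.DataFrame(w, index=names, columns=names))
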