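import numpy as np
import pandas as pd
import pytest

from aquacore import CountTable, SimulationConfig, simulate_community


@pytest.fixture(scope="session")
def small_sim():
    """A reduced planted-structure community shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_background=400)
    return simulate_community(cfg)


@pytest.fixture()
def tiny_table():
    df = pd.DataFrame(
        {"s1": [1, 1, 2], "s2": [5, 0, 5], "s3": [0, 3, 7]},
        index=["asvA", "asvB", "asvC"],
    )
    return CountTable(df)


def random_count_table(rng: np.random.Generator, n_taxa: int, n_samples: int) -> CountTable:
    """Small random table with a mix of abundant and sparse taxa."""
    scale = rng.choice([1.0, 5.0, 40.0], size=n_taxa)
    counts = rng.poisson(scale[:, None] * rng.random((n_taxa, n_samples)))
    ids = [f"t{i:03d}" for i in range(n_taxa)]
    cols = [f"s{j:02d}" for j in range(n_samples)]
    return CountTable(pd.DataFrame(counts, index=ids, columns=cols))
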