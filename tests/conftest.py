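import numpy as np
import pandas as pd
import pytest

import persistome as pm


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study: 8 stages x 3 tanks, 300 taxa, fast."""
    stages = [(f"S{i}", d) for i, d in enumerate([1, 2, 4, 6, 9, 12, 16, 21], 1)]
    return pm.simulate_dataset(n_taxa=300, n_persistent=20, Nt=5000,
                               stages=stages, tanks_per_stage=3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_counts():
    """Tiny deterministic count table with metadata."""
    counts = pd.DataFrame(
        [[30, 10, 5, 0], [25, 12, 0, 3], [28, 9, 4, 1],
         [5, 40, 2, 0], [6, 38, 0, 2], [4, 42, 3, 1]],
        index=[f"s{i}" for i in range(1, 7)],
        columns=["a", "b", "c", "d"])
    metadata = pd.DataFrame({
        "dph": [1, 1, 1, 9, 9, 9],
        "stage": ["early"] * 3 + ["late"] * 3,
        "tank": [1, 2, 3, 1, 2, 3],
        "mass_g": [0.03] * 6,
    }, index=counts.index)
    return pm.CountTable(counts, metadata)
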