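import numpy as np
import pytest

from longcall import SyntheticSpec, generate_feature_table
from longcall.synthetic import feature_columns


@pytest.fixture(scope="session")
def two_blobs():
    """Two tight, well-separated 2-D blobs (20 points each)."""
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(0.0, 0.3, (20, 2)), rng.normal(5.0, 0.3, (20, 2))])
    labels = np.repeat([0, 1], 20)
    return X, labels


@pytest.fixture(scope="session")
def graded_table():
    """Synthetic feature table: two archetype clusters, 10% graded bridge."""
    spec = SyntheticSpec(n_pulses=500, graded_fraction=0.1,
                         n_extra_features=0, seed=7)
    table, truth = generate_feature_table(spec)
    return table, truth, spec


@pytest.fixture(scope="session")
def graded_features(graded_table):
    table, _, _ = graded_table
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return X
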