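import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from metabomark import FeatureTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(values, groups, sample_ids=None, feature_ids=None) -> FeatureTable:
    """Build a FeatureTable from a plain array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j}" for j in range(p)]
    return FeatureTable(
        pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        pd.Series(list(groups), index=sample_ids),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_group_scaled(rng):
    """Centred matrix with two clearly separated classes along feature 0."""
    n = 20
    X = rng.normal(size=(2 * n, 15))
    X[:n, 0] += 7.0
    g = np.array(["case"] * n + ["control"] * n)
    return X - X.mean(axis=0), g
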