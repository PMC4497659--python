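import warnings

import numpy as np
import pandas as pd
import pytest

import autocmap as acm
from autocmap.study import expand_sex_indicator, surrogate_study_dataset

CLASS_COLUMNS = ("AGA", "IUGR")


@pytest.fixture(scope="session")
def surrogate():
    """Synthetic surrogate of the 46-newborn study table (default seed)."""
    return surrogate_study_dataset()


@pytest.fixture(scope="session")
def surrogate_features(surrogate):
    """The 12 non-class columns (sex + 11 quantitative variables)."""
    keep = [v for v in surrogate.variable_names if v not in CLASS_COLUMNS]
    sub = surrogate.select(keep)
    return acm.Dataset(values=sub.values, class_labels=surrogate.class_labels)


@pytest.fixture(scope="session")
def surrogate_expanded(surrogate):
    """Surrogate with the complementary Female indicator added (15 columns)."""
    return expand_sex_indicator(surrogate)


@pytest.fixture(scope="session")
def record_distances(surrogate_features):
    """Record-to-record auto-contractive-map distances of the surrogate."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return acm.record_map(surrogate_features)


@pytest.fixture()
def toy_frame():
    return pd.DataFrame(
        {"a": [0.0, 1.0, 0.2], "b": [1.0, 0.0, 0.4], "c": [0.5, 0.5, 1.0]},
        index=["r1", "r2", "r3"],
    )


def random_distance_matrix(rng: np.random.Generator, n: int) -> pd.DataFrame:
    m = rng.uniform(0.1, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    names = [f"n{i}" for i in range(n)]
    return pd.DataFrame(m, index=names, columns=names)
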