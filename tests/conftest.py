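import numpy as np
import pandas as pd
import pytest

from omicselect.io_tables import FeatureTable, StudyDesign, ViewKind


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """3 samples x 2 features, generic view."""
    df = pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=["s1", "s2", "s3"],
        columns=["fA", "fB"],
    )
    return FeatureTable(df, ViewKind.generic)


@pytest.fixture
def paired_design():
    """Two groups x 3 subjects, days 0 and 10."""
    rows = []
    for g, prefix in ((0, "C"), (1, "T")):
        for i in range(1, 4):
            for day in (0, 10):
                rows.append(
                    {
                        "sample_id": f"{prefix}{i}_d{day}",
                        "subject_id": f"{prefix}{i}",
                        "group": g,
                        "day": day,
                    }
                )
    return StudyDesign(pd.DataFrame(rows))


@pytest.fixture
def labeled_matrix(rng):
    """n=18 two-class matrix with 3 informative features out of 30."""
    n, p = 18, 30
    y = np.array([0] * 9 + [1] * 9)
    X = rng.standard_normal((n, p))
    X[:, :3] += y[:, None] * 2.5
    return X, y
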