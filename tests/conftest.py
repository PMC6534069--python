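import numpy as np
import pandas as pd
import pytest

from triomix.containers import CompositionMatrix, FeatureTable, SampleMetadata


@pytest.fixture
def small_table():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(size=(12, 4)),
        index=[f"S{i}" for i in range(12)],
        columns=[f"v{j}" for j in range(4)],
    )
    return FeatureTable(data)


@pytest.fixture
def small_composition():
    rng = np.random.default_rng(11)
    counts = rng.integers(1, 100, size=(10, 6)).astype(float)
    df = pd.DataFrame(counts, index=[f"S{i}" for i in range(10)],
                      columns=[f"t{j}" for j in range(6)])
    props = df.div(df.sum(axis=1), axis=0)
    return CompositionMatrix(props, counts=df)


@pytest.fixture
def metadata():
    rng = np.random.default_rng(5)
    n = 12
    return SampleMetadata(
        pd.DataFrame({
            "gender": ["F", "M"] * (n // 2),
            "total_kcal": np.exp(rng.normal(np.log(2000), 0.2, n)),
            "batch": ["b1"] * n,
            "bmi": rng.normal(25, 3, n),
        }, index=[f"S{i}" for i in range(n)]),
        required=("gender", "total_kcal"),
    )
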