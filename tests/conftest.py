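import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_qsar(rng):
    """12 compounds x 3 descriptors with a known linear response + noise."""
    X = pd.DataFrame(
        rng.standard_normal((12, 3)),
        columns=["D1", "D2", "D3"],
        index=[f"c{i}" for i in range(12)],
    )
    y = pd.Series(
        1.5 + 2.0 * X["D1"] - 0.7 * X["D2"] + 0.1 * rng.standard_normal(12),
        index=X.index,
    )
    return X, y
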