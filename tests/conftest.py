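import numpy as np
import pandas as pd
import pytest

from proteoage.containers import Contrast, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def log2_matrix_20x6(rng):
    """Fixed 20-feature, 3+3-sample log2 matrix with a few true shifts."""
    data = rng.normal(20.0, 1.0, (20, 6))
    data[:5, 3:] += 1.5
    df = pd.DataFrame(
        data,
        index=[f"F{i:02d}" for i in range(20)],
        columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
    )
    meta = pd.DataFrame(
        {"group": ["A"] * 3 + ["B"] * 3}, index=pd.Index(df.columns, name="sample_id")
    )
    return OmicsMatrix(df, kind="log2", meta=meta)


@pytest.fixture
def contrast_20x6(log2_matrix_20x6):
    return Contrast.from_groups(log2_matrix_20x6, "A", "B")
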