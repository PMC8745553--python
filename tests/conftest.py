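import numpy as np
import pandas as pd
import pytest

from implinet import ExpressionMatrix, HOUSEKEEPING_GENES, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec():
    return SyntheticSpec(seed=7)


@pytest.fixture
def small_expression(rng):
    """60 samples × (5 background + 27 housekeeping) genes, iid Gaussian."""
    genes = [f"G{i:02d}" for i in range(5)] + list(HOUSEKEEPING_GENES)
    values = pd.DataFrame(
        rng.normal(size=(len(genes), 60)),
        index=genes,
        columns=[f"S{j:02d}" for j in range(60)],
    )
    return ExpressionMatrix(values=values)
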