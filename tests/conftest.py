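import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tissuespec.expression_io import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, genes=None, tissues=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    tissues = tissues or [f"t{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=tissues))


@pytest.fixture
def toy_matrix():
    return make_matrix(
        [[150, 0, 2], [5, 5, 5], [0.1, 0.2, 0.0], [300, 50, 0]],
        genes=["spec", "flat", "faint", "near_miss"],
        tissues=["flower", "leaf", "root"],
    )
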