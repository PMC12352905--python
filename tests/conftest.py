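import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from hnfscore import CohortSpec, ExpressionMatrix, simulate_bulk_cohort


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, hand-sized for direct arithmetic."""
    df = pd.DataFrame(
        {
            "s1": [1.0, 0.0, 3.0],
            "s2": [3.0, 0.0, 3.0],
            "s3": [7.0, 0.0, 3.0],
            "s4": [15.0, 0.0, 3.0],
        },
        index=["GENEA", "GENEB", "GENEC"],
    )
    return ExpressionMatrix(df, scale="tpm")


@pytest.fixture
def default_cohort():
    return simulate_bulk_cohort(CohortSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
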