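import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from digitalmarker import DrugResponse, ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20210929)


@pytest.fixture
def small_expression():
    """3 genes x 4 samples with simple TPM values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [9.0, 9.0, 9.0, 9.0],
         [99.0, 99.0, 99.0, 99.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, cancer_type="test", dataset_tag="unit")


def make_continuous_response(samples, z, drug="drugX"):
    """Response with prescribed Z-scores (IC50 backfilled consistently)."""
    z = np.asarray(z, dtype=float)
    return DrugResponse(drug, list(samples), "continuous",
                        ic50=np.exp(z + 5.0), z=z)


@pytest.fixture
def continuous_response(small_expression):
    return make_continuous_response(small_expression.samples,
                                    [-1.0, -0.5, 0.5, 1.0])
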