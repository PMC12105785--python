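import numpy as np
import pandas as pd
import pytest

from dmdtraj.cohort_io import make_cohort
from dmdtraj.model_variants import build_variant
from dmdtraj.populations import default_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort_df():
    rows = [
        ("p1", 5.0, "nsaa", 20.0),
        ("p1", 5.5, "nsaa", 22.0),
        ("p1", 6.0, "walk", 5.2),
        ("p2", 7.25, "nsaa", 25.0),
        ("p2", 8.0, "rff", 3.1),
        ("p3", 10.0, "nsaa", 18.0),
    ]
    return pd.DataFrame(rows, columns=["patient_id", "age_years", "outcome", "value"])


@pytest.fixture
def small_cohort(small_cohort_df):
    return make_cohort(small_cohort_df)


@pytest.fixture
def variant_d():
    return build_variant("D")


@pytest.fixture
def pop_d(variant_d):
    return default_population(variant_d)
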