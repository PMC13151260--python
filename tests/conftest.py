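import warnings

import numpy as np
import pandas as pd
import pytest

from gaitcausal.cohort import BinaryDesign, make_binary_design
from gaitcausal.simulate import (default_cohort_spec, generate_cohort,
                                 generate_screening_fixture)


@pytest.fixture(scope="session")
def screening_records():
    return generate_screening_fixture(seed=42)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The 126-patient synthetic cohort used throughout the suite."""
    return generate_cohort(default_cohort_spec(126, seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """A 5,000-patient cohort for parameter-recovery checks."""
    return generate_cohort(default_cohort_spec(5000, seed=7))


@pytest.fixture(scope="session")
def large_design(large_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_binary_design(large_cohort)


def binary_design_from_arrays(X: np.ndarray, y: np.ndarray,
                              names: list[str] | None = None) -> BinaryDesign:
    """Wrap raw 0/1 arrays as a BinaryDesign for model-level tests."""
    X = np.atleast_2d(np.asarray(X, dtype=int))
    if names is None:
        names = [f"v{i}" for i in range(X.shape[1])]
    return BinaryDesign(pd.DataFrame(X, columns=names),
                        np.asarray(y, dtype=int), {})
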