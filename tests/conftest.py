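import numpy as np
import pytest

from cohortcluster.cohort import CohortMatrix, TraitTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(X, ages=None, ids=None, names=None, mask=None):
    X = np.asarray(X, float)
    n, p = X.shape
    return CohortMatrix(
        sample_ids=ids if ids is not None else np.array([f"s{i:04d}" for i in range(n)]),
        ages=ages if ages is not None else np.full(n, 45.0),
        markers=X,
        marker_names=names if names is not None else [f"m{j:02d}" for j in range(p)],
        missing_mask=mask,
    )


def make_traits(values, ids=None, names=None):
    values = np.asarray(values, float)
    n, t = values.shape
    return TraitTable(
        sample_ids=ids if ids is not None else np.array([f"s{i:04d}" for i in range(n)]),
        trait_names=names if names is not None else [f"t{j:02d}" for j in range(t)],
        values=values,
    )


@pytest.fixture
def blob_cohort(rng):
    """Two well-separated blobs (n=60, P=6) with truth labels."""
    truth = np.repeat([1, 2], 30)
    cents = np.array([[3.0, -3, 3, -3, 3, -3], [-3.0, 3, -3, 3, -3, 3]])
    X = cents[truth - 1] + rng.normal(0, 1, (60, 6))
    return make_cohort(X), truth
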