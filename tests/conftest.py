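import numpy as np
import pytest

from cohortqc import CohortSpec, generate_cohort, prepare_variants
from cohortqc.datasets import PreparedDataset


def make_prepared(X, adjusted=False):
    """Wrap a standardized matrix as a PreparedDataset for detector tests."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    return PreparedDataset(
        ids=[f"S{i:03d}" for i in range(n)],
        variable_names=[f"v{j}" for j in range(p)],
        values=X,
        imputed_mask=np.zeros((n, p), dtype=bool),
        centers=np.zeros(p),
        scales=np.ones(p),
        adjusted=adjusted,
    )


def standardized(X):
    X = np.asarray(X, dtype=float)
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by integration-style tests."""
    spec = CohortSpec(n=120, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_variants(small_cohort):
    data, cov = small_cohort
    return prepare_variants(data, cov)
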