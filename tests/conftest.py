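import numpy as np
import pytest

from lassologit.cohort import encode_design, read_cohort
from lassologit.simulate import packaged_cohort_path


@pytest.fixture(scope="session")
def cohort339():
    return read_cohort(packaged_cohort_path())


@pytest.fixture(scope="session")
def dm339(cohort339):
    return encode_design(cohort339)


@pytest.fixture(scope="session")
def toy_logistic():
    """n=200, p=8 logistic dataset with true support {0, 1, 4}."""
    rng = np.random.default_rng(0)
    n, p = 200, 8
    X = rng.standard_normal((n, p))
    beta = np.array([1.5, -1.0, 0.0, 0.0, 0.8, 0.0, 0.0, 0.0])
    prob = 1.0 / (1.0 + np.exp(-(0.3 + X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    return X, y, beta
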