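import numpy as np
import pytest

from liureg import DesignResponse, fit_ols


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_design(rng):
    """A well-conditioned 40 x 5 design with mildly correlated columns."""
    base = rng.standard_normal((40, 5))
    base[:, 1] += 0.5 * base[:, 0]
    y = base @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.standard_normal(40)
    return DesignResponse(X=base, y=y, intercept=False)


@pytest.fixture
def random_fit(random_design):
    return fit_ols(random_design)
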