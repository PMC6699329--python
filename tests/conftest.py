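import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def std_problem(rng):
    """A standardized sparse regression instance (n=40, p=8, 3 signals)."""
    from nirsparse.data import SpectraDataset, standardize

    X = rng.standard_normal((40, 8))
    beta = np.zeros(8)
    beta[:3] = 2.0
    y = X @ beta + rng.standard_normal(40)
    data = SpectraDataset(X=X, y=y)
    Xs, ys, state = standardize(data)
    return Xs, ys, state, data
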