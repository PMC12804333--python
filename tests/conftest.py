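import numpy as np
import pytest
from hypothesis import settings

from survmctp import SurvivalData

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_pair() -> SurvivalData:
    """Two subjects, one per group, events at t=1 and t=2.

    Hand computation: only t=1 contributes to the pairwise statistic,
    giving T(w=1) = -sqrt(2)/2, Sigma = 0.5, Z = 1.
    """
    return SurvivalData.from_arrays([1.0, 2.0], [1, 1], ["a", "b"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def make_null_data(rng, k=2, n=30, rate=1.0, censor_upper=None) -> SurvivalData:
    """k exponential groups with identical law (global null)."""
    t = rng.exponential(1.0 / rate, size=k * n)
    if censor_upper is None:
        d = np.ones(k * n, dtype=int)
        x = t
    else:
        c = rng.uniform(0, censor_upper, size=k * n)
        x = np.minimum(t, c)
        d = (t <= c).astype(int)
    g = np.repeat(np.arange(1, k + 1), n)
    return SurvivalData.from_arrays(x, d, g)
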