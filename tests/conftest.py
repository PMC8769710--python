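import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from survfilter import SurvivalDataset
from survfilter.synthetic import SynthConfig, generate

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_dataset() -> SurvivalDataset:
    """3 observations, 1 feature; the worked-example fixture."""
    return SurvivalDataset(
        np.array([[1.0], [2.0], [3.0]]),
        ("x",),
        np.array([2.0, 5.0, 7.0]),
        np.array([1, 1, 0]),
    )


@pytest.fixture
def random_dataset():
    """Factory for small random survival data sets (seeded)."""

    def make(seed: int, n: int = 25, p: int = 4, event_p: float = 0.6, ties: bool = False):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        t = rng.exponential(1.0, n) + 0.05
        if ties:
            t = np.round(t, 1) + 0.1
        e = (rng.uniform(size=n) < event_p).astype(int)
        if e.sum() == 0:
            e[0] = 1
        return SurvivalDataset(X, tuple(f"f{j}" for j in range(p)), t, e)

    return make


@pytest.fixture
def strong_signal_small():
    """n=200, p=20 synthetic fixture with 3 informative features in
    distinct correlated blocks; factory over seeds."""

    def make(seed: int):
        return generate(
            SynthConfig(n=200, p=20, n_informative=3, block_size=5, seed=seed)
        )

    return make
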