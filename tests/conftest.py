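import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from seasonwave import WeeklySeries

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        # fixtures used with @given are pure stateless factories
        HealthCheck.function_scoped_fixture,
    ],
    deadline=None,
)
settings.load_profile("repro")


@pytest.fixture
def weekly_index():
    """Factory for uniform weekly DatetimeIndex grids."""

    def make(n: int, start: str = "2012-08-05") -> pd.DatetimeIndex:
        return pd.date_range(start, periods=n, freq="7D")

    return make


@pytest.fixture
def cosine_series(weekly_index):
    """Factory for cosine-seasonal weekly series with optional white noise."""

    def make(
        n: int = 261,
        period: float = 52.0,
        amplitude: float = 10.0,
        base: float = 60.0,
        peak_week: float = 26.0,
        noise_sd: float = 0.0,
        seed: int = 0,
        term: str = "cosine",
    ) -> WeeklySeries:
        t = np.arange(n)
        x = base + amplitude * np.cos(2 * np.pi * (t - peak_week) / period)
        if noise_sd:
            x = x + np.random.default_rng(seed).normal(0.0, noise_sd, n)
        return WeeklySeries(term, weekly_index(n), np.clip(x, 0, None))

    return make
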