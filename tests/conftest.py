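import numpy as np
import pandas as pd
import pytest

import edwarn as ew


@pytest.fixture(scope="session")
def seasonal_series():
    """Noisy sinusoidal hourly series with a 24-hour cycle, 500 points."""
    rng = np.random.default_rng(11)
    n = 500
    y = 50 + 12 * np.sin(2 * np.pi * np.arange(n) / 24) + rng.normal(0, 2, n)
    idx = pd.date_range("2022-01-01", periods=n, freq="h")
    return pd.Series(y, index=idx)


@pytest.fixture(scope="session")
def small_ed():
    """30 days of synthetic arrivals + occupancy (default generator)."""
    return ew.simulate_ed(30, seed=123)
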