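import numpy as np
import pandas as pd
import pytest

from ccwin import DailySeries, SimulationConfig, generate_study_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series(rng):
    """Four consecutive days with simple values."""
    return DailySeries(
        dates=pd.date_range("2019-01-01", periods=4, freq="D"),
        outcome=[3.0, 1.0, 2.0, 5.0],
        exposure=[10.0, 12.0, 9.0, 11.0],
    )


@pytest.fixture
def year_series(rng):
    """One 365-day year of continuous data."""
    n = 365
    return DailySeries(
        dates=pd.date_range("2001-01-01", periods=n, freq="D"),
        outcome=rng.normal(size=n),
        exposure=rng.normal(size=n),
    )


def random_stratified_frame(rng, family, n_strata=None, min_days=2, max_days=5):
    """Random small stratified dataset for oracle-equivalence checks."""
    if n_strata is None:
        n_strata = int(rng.integers(2, 11))
    rows = []
    for s in range(n_strata):
        for _ in range(int(rng.integers(min_days, max_days + 1))):
            x = float(rng.normal())
            y = float(rng.poisson(3.0)) if family == "poisson" else float(rng.normal())
            rows.append((f"s{s:02d}", x, y))
    return pd.DataFrame(rows, columns=["stratum", "x", "y"])


@pytest.fixture(scope="session")
def sim1_samples_50():
    return generate_study_set(SimulationConfig(sim_id=1, seed=1), 50)


@pytest.fixture(scope="session")
def sim2_samples_50():
    return generate_study_set(SimulationConfig(sim_id=2, seed=1), 50)
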