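import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bloomscan.dataset import WeeklyTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_weekly_table(
    factors: dict[str, np.ndarray],
    week_indices: np.ndarray | None = None,
    start: str = "2015-01-05 10:00",
) -> WeeklyTable:
    """Construct a weekly table directly from per-factor arrays.

    ``week_indices`` lets tests punch holes into the lattice; dates are
    placed 7 days apart on it so calendar fields stay consistent.
    """
    n = len(next(iter(factors.values())))
    wi = np.arange(n) if week_indices is None else np.asarray(week_indices)
    dates = pd.Timestamp(start) + pd.to_timedelta(7 * wi, unit="D")
    frame = pd.DataFrame(
        {
            "date": dates,
            "year": dates.year,
            "month": dates.month,
            "day": dates.day,
            "week_index": wi,
        }
    )
    for name, values in factors.items():
        frame[name] = np.asarray(values, dtype=float)
    return WeeklyTable(frame)


@pytest.fixture(scope="session")
def weekly_scenario():
    """One seeded weekly-cadence scenario spanning 2015-2022."""
    from bloomscan.synthetic import ScenarioConfig, generate_scenario

    config = ScenarioConfig(seed=11, include_sensor_channels=False)
    return config, generate_scenario(config)


@pytest.fixture(scope="session")
def weekly_table(weekly_scenario):
    from bloomscan.dataset import to_weekly

    _, series = weekly_scenario
    return to_weekly(series)
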