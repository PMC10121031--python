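import datetime as dt

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_records(minutes, station="S001", species="tiger_cat", start=None):
    """Record table with events at the given minute offsets from a base time."""
    start = start or dt.datetime(2018, 8, 1, 10, 0)
    return pd.DataFrame(
        {
            "station_id": station,
            "species": species,
            "timestamp": [start + dt.timedelta(minutes=float(m)) for m in minutes],
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused by pipeline-level tests."""
    from camcooccur.synth import SimulationConfig, simulate_study

    return simulate_study(SimulationConfig(seed=42, n_stations=14, n_surveys=4))
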