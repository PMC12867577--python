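import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from calokit.frame import CalorimetryFrame
from calokit.metadata import Photoperiod

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def photoperiod():
    return Photoperiod(dt.time(7, 0), dt.time(19, 0))


def make_frame(n_animals=2, n_samples=24, interval_min=60, vo2=1000.0,
               vco2=800.0, start="2024-01-01 07:00:00", **extra_channels):
    """Deterministic constructed frame: constant gas rates per animal."""
    def at(values, i):
        return values[i] if hasattr(values, "__len__") else values

    rows = []
    t0 = pd.Timestamp(start)
    for a in range(n_animals):
        animal = f"A{a + 1}"
        for i in range(n_samples):
            row = {
                "animal_id": animal,
                "cohort_id": "c1",
                "timestamp": t0 + pd.Timedelta(minutes=interval_min * i),
                "vo2": at(vo2, i),
                "vco2": at(vco2, i),
            }
            for ch, values in extra_channels.items():
                row[ch] = at(values, i)
            rows.append(row)
    return CalorimetryFrame(pd.DataFrame(rows))


@pytest.fixture
def small_frame():
    return make_frame()


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
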