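import numpy as np
import pandas as pd
import pytest

from sporekernel import GutPassageResults, Track

EPOCH = np.datetime64("2016-07-01T00:00:00", "ns")


def hours_to_times(hours):
    """Absolute timestamps at the given hour offsets from a fixed epoch."""
    return EPOCH + (np.asarray(hours, dtype=float) * 3.6e12).astype("timedelta64[ns]")


def projected_track(hours, x_m, y_m=None, animal="a1", period="p1"):
    """Track in projected-metre coordinates (Euclidean distances, exact)."""
    x_m = np.asarray(x_m, dtype=float)
    y_m = np.zeros_like(x_m) if y_m is None else np.asarray(y_m, dtype=float)
    return Track(
        animal_id=animal, period_id=period,
        times=hours_to_times(hours), lat=y_m, lon=x_m, crs="projected",
    )


def gut_results(t50=30.0, s=6.0, window_hours=69.0, trial="trial"):
    """Gut-passage results with exact known parameters (no fitting)."""
    return GutPassageResults.from_dict({
        "trial_animal_id": trial, "t50_h": t50, "s_h": s,
        "window_hours": window_hours,
    })


@pytest.fixture
def gut30_6():
    return gut_results(30.0, 6.0)


@pytest.fixture
def telemetry_csv(tmp_path):
    """Small valid telemetry CSV: one animal, one period, four fixes."""
    df = pd.DataFrame({
        "animal_id": ["a1"] * 4,
        "period_id": ["p1"] * 4,
        "timestamp": pd.date_range("2016-07-01", periods=4, freq="30min").astype(str),
        "lat": [-30.4, -30.401, -30.402, -30.403],
        "lon": [151.6, 151.601, 151.602, 151.603],
    })
    path = tmp_path / "telemetry.csv"
    df.to_csv(path, index=False)
    return path
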