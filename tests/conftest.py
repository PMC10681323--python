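from datetime import date

import pandas as pd
import pytest

from reeftrace import StudyConfig


@pytest.fixture
def config():
    return StudyConfig(study_start=date(2015, 1, 1), study_end=date(2016, 12, 31))


@pytest.fixture
def stations():
    """Three stations on two islands with simple geometry."""
    return pd.DataFrame(
        {
            "station_id": ["A", "B", "C"],
            "island": ["I1", "I1", "I2"],
            "lat": [19.30, 19.35, 19.70],
            "lon": [-81.20, -81.20, -80.00],
        }
    )


def make_detections(rows):
    """Build a resolved detection frame from (timestamp, station, tag, island)."""
    df = pd.DataFrame(rows, columns=["timestamp", "station_id", "tag_id", "island"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.normalize()
    return df[["timestamp", "date", "tag_id", "station_id", "island"]]


def days_of_detections(tag, days, per_day=2, station="A", island="I1", start_hour=8):
    """n detections per listed day, spaced a minute apart."""
    rows = []
    for d in days:
        base = pd.Timestamp(d) + pd.Timedelta(hours=start_hour)
        for k in range(per_day):
            rows.append((base + pd.Timedelta(minutes=k), station, tag, island))
    return make_detections(rows)
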