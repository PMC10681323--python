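"""Detection pre-processing.

Raw receiver downloads are standardised before any metric is computed:

1. duplicate rows (same tag, serial, timestamp) from overlapping
   downloads are dropped;
2. each serial is resolved to the station where it was moored at the
   detection time using the deployment calendar, and timestamps are
   shifted to local time with a fixed UTC offset;
3. detections at stations that carried a functioning receiver for less
   than six months are discarded;
4. "single detections" - a tag heard exactly once array-wide on a local
   calendar day - are removed as likely false detections. The rule is
   applied per tag per day because such a detection can never form a
   detection day (which requires two or more detections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from .errors import DataIntegrityError

#: Columns of a resolved detection frame.
DETECTION_COLUMNS = ["timestamp", "date", "tag_id", "station_id", "island"]


@dataclass
class ResolveReport:
    """Bookkeeping from :func:`resolve_stations`."""

    n_input: int = 0
    n_duplicates: int = 0
    n_unresolved: int = 0  # no deployment interval covered the timestamp
    n_output: int = 0
    duplicates_by_tag: dict = field(default_factory=dict)


def resolve_stations(
    raw: pd.DataFrame,
    deployments: pd.DataFrame,
    stations: pd.DataFrame,
    config: StudyConfig,
) -> tuple[pd.DataFrame, ResolveReport]:
    """Map raw detections onto stations and local time.

    ``raw`` must have columns ``timestamp_utc``, ``receiver_serial``,
    ``tag_code``. Detections whose serial has no covering deployment
    interval are dropped and counted; a serial covered by two intervals
    at once raises :class:`DataIntegrityError` (already guarded at load
    time, re-checked here).
    """
    report = ResolveReport(n_input=len(raw))
    if raw.empty:
        empty = pd.DataFrame(columns=DETECTION_COLUMNS)
        return empty, report

    df = raw.copy()
    dupes = df.duplicated(subset=["timestamp_utc", "receiver_serial", "tag_code"])
    if dupes.any():
        report.n_duplicates = int(dupes.sum())
        report.duplicates_by_tag = (
            df.loc[dupes, "tag_code"].value_counts().to_dict()
        )
        df = df[~dupes]

    df["timestamp"] = df["timestamp_utc"] + pd.Timedelta(hours=config.utc_offset_hours)
    df["date"] = df["timestamp"].dt.normalize()

    station_id = np.full(len(df), None, dtype=object)
    dates = df["date"].values
    for serial, grp in df.groupby("receiver_serial"):
        cal = deployments[deployments["receiver_serial"] == serial]
        if cal.empty:
            continue
        cal = cal.sort_values("start_date")
        starts = cal["start_date"].values
        ends = cal["end_date"].fillna(pd.Timestamp.max).values
        idx = df.index.get_indexer(grp.index)
        pos = np.searchsorted(starts, dates[idx], side="right") - 1
        ok = pos >= 0
        ok[ok] &= dates[idx][ok] <= ends[pos[ok]]
        # a second interval also covering the date would violate the
        # non-overlap invariant; detect it defensively
        nxt = pos + 1
        bad = ok & (nxt < len(starts))
        if bad.any() and (starts[nxt[bad]] <= dates[idx][bad]).any():
            raise DataIntegrityError(f"serial {serial}: overlapping deployment intervals")
        station_id[idx[ok]] = cal["station_id"].values[pos[ok]]

    df["station_id"] = station_id
    unresolved = df["station_id"].isna()
    report.n_unresolved = int(unresolved.sum())
    df = df[~unresolved]

    island = stations.set_index("station_id")["island"]
    unknown = set(df["station_id"]) - set(island.index)
    if unknown:
        raise DataIntegrityError(f"deployment calendar references unknown stations {sorted(unknown)}")
    df = df.rename(columns={"tag_code": "tag_id"})
    df["island"] = df["station_id"].map(island)
    out = df[DETECTION_COLUMNS].reset_index(drop=True)
    report.n_output = len(out)
    return out, report


def remove_single_detections(dets: pd.DataFrame) -> pd.DataFrame:
    """Drop detections of a tag on days with exactly one detection array-wide.

    Idempotent: days retain either >= 2 detections or none.
    """
    if dets.empty:
        return dets.copy()
    counts = dets.groupby(["tag_id", "date"])["station_id"].transform("size")
    return dets[counts >= 2].reset_index(drop=True)


def station_working_days(
    deployments: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Count working days per station within the study window.

    A deployment ``[d1, d2]`` contributes ``d2 - d1 + 1`` days (both
    ends inclusive), clipped to ``[study_start, study_end]`` and with
    overlaps across a station's intervals counted once. Stations with
    fewer than ``min_station_months * 30`` working days are flagged
    ``excluded``.
    """
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    rows = []
    for station, grp in deployments.groupby("station_id"):
        days: set = set()
        for _, dep in grp.iterrows():
            d1 = max(dep["start_date"], start)
            d2 = min(dep["end_date"] if pd.notna(dep["end_date"]) else end, end)
            if d1 <= d2:
                days.update(pd.date_range(d1, d2, freq="D"))
        rows.append({"station_id": station, "working_days": len(days)})
    out = pd.DataFrame(rows, columns=["station_id", "working_days"])
    out["excluded"] = out["working_days"] < config.min_station_days
    return out.sort_values("station_id").reset_index(drop=True)


def station_month_working_days(
    deployments: pd.DataFrame, config: StudyConfig
) -> pd.Series:
    """Total working days of all stations per calendar month (1..12),
    aggregated across years of the study window."""
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    totals = pd.Series(0, index=pd.RangeIndex(1, 13, name="month"))
    for station, grp in deployments.groupby("station_id"):
        days: set = set()
        for _, dep in grp.iterrows():
            d1 = max(dep["start_date"], start)
            d2 = min(dep["end_date"] if pd.notna(dep["end_date"]) else end, end)
            if d1 <= d2:
                days.update(pd.date_range(d1, d2, freq="D"))
        if days:
            months = pd.Series([d.month for d in days]).value_counts()
            totals = totals.add(months, fill_value=0)
    return totals.astype(int)


def filter_excluded_stations(
    dets: pd.DataFrame, working: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Drop detections at stations excluded by the six-month rule."""
    keep_ids = set(working.loc[~working["excluded"], "station_id"])
    mask = dets["station_id"].isin(keep_ids)
    return dets[mask].reset_index(drop=True), int((~mask).sum())
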