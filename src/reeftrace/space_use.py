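"""Geodesic displacement and space-use indices.

Site fidelity is measured per shark and station with a Detection Index

    DI = (detections at station / shark's total detections)
       x (detection days at station / shark's total detection days)

normalised into a Site-Fidelity Index SFI = DI / sum(DI) x 100; the
rank-1 station is the shark's "primary site". Minimum linear
displacement (MLD) is the great-circle distance between the two most
distant detecting stations plus one detection radius at each end
(0.3 km x 2); a shark seen on a single station gets the distance from
its tagging location plus a single radius.

The Utilization Index ranks stations as implemented in the source
formula: UI = (sharks at station / total detected sharks) x (station
days / total detection days in the array), where station days =
detection days at the station / working days. The index mixes a ratio
with a count and is meaningful for relative ranking only. The monthly
Activity Index is the product of the proportion of detection days and
the proportion of detected sharks in each calendar month.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import StudyConfig
from .errors import ConfigurationError, MetadataError
from .io import SharkRecord

EARTH_RADIUS_KM = 6371.0
DETECTION_RADIUS_KM = 0.3
LONG_DISTANCE_KM = 50.0


def great_circle_km(
    lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM
) -> np.ndarray | float:
    """Haversine great-circle distance in km on a sphere.

    Accepts scalars or arrays; symmetric; zero only for identical
    points.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if (np.abs(lat1) > 90).any() or (np.abs(lat2) > 90).any():
        raise ConfigurationError("latitude outside [-90, 90]")
    if (np.abs(lon1) > 180).any() or (np.abs(lon2) > 180).any():
        raise ConfigurationError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class MLDResult:
    tag_id: str
    mld_km: float
    endpoint_a: str  # station id, or "tagging-location"
    endpoint_b: str
    n_islands: int
    long_distance: bool


def station_usage(dets: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Per-station usage, DI, SFI and rank for one shark.

    Station-level detection days require at least
    ``config.station_day_min_detections`` detections at that station on
    the day (mirroring the array-wide detection-day rule). Ties in SFI
    are broken by station id so the ranking is reproducible.
    """
    if dets.empty:
        raise MetadataError("station_usage: shark has no detections")
    per_station = dets.groupby("station_id").size().rename("n_detections")
    per_day = dets.groupby(["station_id", "date"]).size()
    st_days = (
        (per_day >= config.station_day_min_detections)
        .groupby("station_id")
        .sum()
        .rename("n_detection_days")
    )
    usage = pd.concat([per_station, st_days], axis=1).fillna(0).reset_index()
    usage["n_detection_days"] = usage["n_detection_days"].astype(int)

    total_dets = usage["n_detections"].sum()
    total_days = usage["n_detection_days"].sum()
    if total_days == 0:
        raise MetadataError(
            "station_usage: no station accumulated a detection day for this shark"
        )
    usage["di"] = (usage["n_detections"] / total_dets) * (
        usage["n_detection_days"] / total_days
    )
    usage["sfi"] = usage["di"] / usage["di"].sum() * 100.0
    usage = usage.sort_values(["sfi", "station_id"], ascending=[False, True])
    usage["rank"] = np.arange(1, len(usage) + 1)
    return usage.reset_index(drop=True)


def minimum_linear_displacement(
    dets: pd.DataFrame,
    shark: SharkRecord,
    stations: pd.DataFrame,
    detection_radius_km: float = DETECTION_RADIUS_KM,
) -> MLDResult:
    """Linear home-range proxy for one shark.

    With two or more distinct detecting stations the farthest pair is
    found by exhaustive search and padded with ``2 x radius``; with a
    single detecting station the distance from the tagging location is
    padded with one radius.
    """
    if dets.empty:
        raise MetadataError(f"tag {shark.tag_id}: MLD undefined without detections")
    coords = stations.set_index("station_id")
    used = sorted(dets["station_id"].unique())
    n_islands = dets["island"].nunique()
    if len(used) == 1:
        st = coords.loc[used[0]]
        d = great_circle_km(shark.tagging_lat, shark.tagging_lon, st["lat"], st["lon"])
        mld = d + detection_radius_km
        a, b = "tagging-location", used[0]
    else:
        lat = coords.loc[used, "lat"].values
        lon = coords.loc[used, "lon"].values
        best, a, b = -1.0, used[0], used[1]
        for i in range(len(used)):
            d = great_circle_km(lat[i], lon[i], lat, lon)
            j = int(np.argmax(d))
            if d[j] > best:
                best, a, b = float(d[j]), used[i], used[j]
        mld = best + 2.0 * detection_radius_km
    return MLDResult(
        tag_id=shark.tag_id,
        mld_km=float(mld),
        endpoint_a=a,
        endpoint_b=b,
        n_islands=int(n_islands),
        long_distance=bool(mld > LONG_DISTANCE_KM),
    )


def utilization_index(
    dets: pd.DataFrame, working: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Station-level Utilization Index over the whole study.

    ``working`` is the output of
    :func:`reeftrace.preprocess.station_working_days`. Stations with
    zero working days are excluded (a UI denominator of zero is
    meaningless); stations that detected no shark get UI = 0.
    """
    if "excluded" in working.columns:
        working = working[~working["excluded"]]
    working = working[working["working_days"] > 0]

    # a station detection day is a (shark, day) pair with enough
    # detections at the station; days of different sharks accumulate
    per_day = dets.groupby(["station_id", "tag_id", "date"]).size()
    st_days = (
        (per_day >= config.station_day_min_detections).groupby("station_id").sum()
    )
    n_sharks = dets.groupby("station_id")["tag_id"].nunique()

    total_sharks = dets["tag_id"].nunique()
    total_days = int(st_days.sum())

    out = working[["station_id", "working_days"]].copy()
    out["n_detection_days"] = out["station_id"].map(st_days).fillna(0).astype(int)
    out["n_sharks"] = out["station_id"].map(n_sharks).fillna(0).astype(int)
    out["station_days"] = out["n_detection_days"] / out["working_days"]
    if total_sharks == 0 or total_days == 0:
        out["ui"] = 0.0
    else:
        out["ui"] = (out["n_sharks"] / total_sharks) * (out["station_days"] / total_days)
    return out.sort_values("station_id").reset_index(drop=True)


def activity_index(
    dets: pd.DataFrame,
    month_working_days: pd.Series,
    n_detected_sharks: Optional[int] = None,
) -> pd.DataFrame:
    """Monthly Activity Index aggregated across years.

    AI(month) = (detection days in month / working days of all stations
    in month) x (sharks detected in month / total detected sharks).
    Months with zero working days get an absent (NaN) AI.
    """
    if n_detected_sharks is None:
        n_detected_sharks = int(dets["tag_id"].nunique())
    per_day = dets.groupby(["tag_id", "date"]).size()
    day_index = per_day.index[per_day >= 2]
    det_days = pd.DataFrame(
        {"month": [d.month for _, d in day_index], "tag_id": [t for t, _ in day_index]}
    )
    months = pd.RangeIndex(1, 13, name="month")
    n_days = det_days.groupby("month").size().reindex(months, fill_value=0)
    n_sharks = det_days.groupby("month")["tag_id"].nunique().reindex(months, fill_value=0)

    out = pd.DataFrame(
        {
            "working_days": month_working_days.reindex(months, fill_value=0),
            "n_detection_days": n_days,
            "n_sharks": n_sharks,
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["prop_detection_days"] = np.where(
            out["working_days"] > 0, out["n_detection_days"] / out["working_days"], np.nan
        )
    out["prop_sharks"] = (
        out["n_sharks"] / n_detected_sharks if n_detected_sharks else np.nan
    )
    out["ai"] = out["prop_detection_days"] * out["prop_sharks"]
    return out.reset_index()
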