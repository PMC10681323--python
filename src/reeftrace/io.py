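"""Reading and validating the four pipeline input tables.

Detection exports follow the receiver-download convention: a timestamp
column in UTC, a receiver column like ``VR2W-123456`` and a transmitter
column like ``A69-1602-28955``; the token after the final hyphen is the
serial / tag id. Column names and the separator are configurable via
:class:`DetectionDialect` so other download dialects can be parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError, RowParseError

ISLANDS_CAYMAN = ("GC", "LC", "CB")


@dataclass(frozen=True)
class DetectionDialect:
    """Column layout of a detection CSV export."""

    timestamp_col: str = "Date and Time (UTC)"
    receiver_col: str = "Receiver"
    transmitter_col: str = "Transmitter"
    id_separator: str = "-"

    def extract_id(self, value: str) -> str:
        """Return the trailing token of a receiver/transmitter code."""
        return str(value).rsplit(self.id_separator, 1)[-1].strip()


DEFAULT_DIALECT = DetectionDialect()


class RowIssue(NamedTuple):
    line: int  # 1-based line number in the file (header = line 1)
    reason: str


@dataclass(frozen=True)
class SharkRecord:
    """Tag and biological metadata keying all per-individual metrics."""

    tag_id: str
    sex: str  # 'F' or 'M'
    maturity: str  # 'IM' or 'M'
    tl_cm: float
    tagging_date: date
    tagging_lat: float
    tagging_lon: float
    tagging_island: str
    tag_type: str  # 'V9' or 'V16'
    tag_life_days: int

    def __post_init__(self) -> None:
        if not 30 < self.tl_cm < 400:
            raise ConfigurationError(f"tag {self.tag_id}: implausible TL {self.tl_cm} cm")
        if self.tag_life_days <= 0:
            raise ConfigurationError(f"tag {self.tag_id}: tag_life_days must be positive")

    @classmethod
    def from_row(cls, row: pd.Series) -> "SharkRecord":
        return cls(
            tag_id=str(row["tag_id"]),
            sex=str(row["sex"]),
            maturity=str(row["maturity"]),
            tl_cm=float(row["tl_cm"]),
            tagging_date=pd.Timestamp(row["tagging_date"]).date(),
            tagging_lat=float(row["tagging_lat"]),
            tagging_lon=float(row["tagging_lon"]),
            tagging_island=str(row["island"]),
            tag_type=str(row["tag_type"]),
            tag_life_days=int(row["tag_life_days"]),
        )


def load_detections(
    path: str | Path,
    dialect: DetectionDialect = DEFAULT_DIALECT,
    tolerance: float = 0.05,
) -> tuple[pd.DataFrame, list[RowIssue]]:
    """Load a raw detection export.

    Returns a frame with columns ``timestamp_utc``, ``receiver_serial``
    and ``tag_code`` (file order preserved) plus the list of rejected
    rows with their line numbers. Raises :class:`RowParseError` when the
    rejected fraction exceeds ``tolerance`` and
    :class:`ConfigurationError` when a dialect column is missing.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [
        c
        for c in (dialect.timestamp_col, dialect.receiver_col, dialect.transmitter_col)
        if c not in raw.columns
    ]
    if missing:
        raise ConfigurationError(f"{path}: missing detection columns {missing}")

    ts = pd.to_datetime(raw[dialect.timestamp_col], errors="coerce", format="mixed")
    serial = raw[dialect.receiver_col].map(dialect.extract_id, na_action="ignore")
    tag = raw[dialect.transmitter_col].map(dialect.extract_id, na_action="ignore")

    bad = ts.isna() | serial.isna() | (serial == "") | tag.isna() | (tag == "")
    issues: list[RowIssue] = []
    for idx in raw.index[bad]:
        if pd.isna(ts.iloc[idx]):
            reason = f"unparseable timestamp {raw[dialect.timestamp_col].iloc[idx]!r}"
        else:
            reason = "empty receiver or transmitter field"
        issues.append(RowIssue(line=int(idx) + 2, reason=reason))

    n = len(raw)
    if n and len(issues) / n > tolerance:
        raise RowParseError(
            f"{path}: {len(issues)}/{n} malformed rows exceeds tolerance {tolerance:.0%}"
        )
    out = pd.DataFrame(
        {
            "timestamp_utc": ts[~bad],
            "receiver_serial": serial[~bad],
            "tag_code": tag[~bad],
        }
    ).reset_index(drop=True)
    return out, issues


def load_stations(path: str | Path) -> pd.DataFrame:
    """Load the station table (``station_id,island,lat,lon``)."""
    df = pd.read_csv(path, dtype={"station_id": str, "island": str})
    _require(df, path, ["station_id", "island", "lat", "lon"])
    if df["station_id"].duplicated().any():
        dupes = df.loc[df["station_id"].duplicated(), "station_id"].tolist()
        raise DataIntegrityError(f"{path}: duplicate station ids {dupes}")
    if not df["lat"].between(-90, 90).all() or not df["lon"].between(-180, 180).all():
        raise DataIntegrityError(f"{path}: coordinates outside valid WGS84 ranges")
    return df


def load_deployments(path: str | Path) -> pd.DataFrame:
    """Load the receiver deployment calendar.

    ``receiver_serial,station_id,start_date,end_date`` with an empty
    end date meaning the deployment is still open. Intervals for one
    serial (and for one station) must not overlap.
    """
    df = pd.read_csv(path, dtype={"receiver_serial": str, "station_id": str})
    _require(df, path, ["receiver_serial", "station_id", "start_date", "end_date"])
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])  # NaT = open-ended
    closed = df["end_date"].notna()
    if (df.loc[closed, "end_date"] < df.loc[closed, "start_date"]).any():
        raise DataIntegrityError(f"{path}: deployment with end_date before start_date")
    for key in ("receiver_serial", "station_id"):
        for name, grp in df.groupby(key):
            grp = grp.sort_values("start_date")
            ends = grp["end_date"].fillna(pd.Timestamp.max)
            # inclusive dates: the next interval must start strictly after
            if (grp["start_date"].iloc[1:].values <= ends.iloc[:-1].values).any():
                raise DataIntegrityError(f"{path}: overlapping intervals for {key}={name}")
    return df


def load_sharks(path: str | Path) -> pd.DataFrame:
    """Load shark/tag metadata and validate each record."""
    df = pd.read_csv(path, dtype={"tag_id": str, "sex": str, "maturity": str})
    _require(
        df,
        path,
        [
            "tag_id",
            "sex",
            "maturity",
            "tl_cm",
            "tagging_date",
            "tagging_lat",
            "tagging_lon",
            "island",
            "tag_type",
            "tag_life_days",
        ],
    )
    if df["tag_id"].duplicated().any():
        raise DataIntegrityError(f"{path}: duplicate tag ids")
    df["tagging_date"] = pd.to_datetime(df["tagging_date"])
    for _, row in df.iterrows():
        SharkRecord.from_row(row)  # raises on invalid metadata
    return df


def _require(df: pd.DataFrame, path, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}")
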