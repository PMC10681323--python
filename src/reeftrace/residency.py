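"""Residency metrics and the rule-based residency classifier.

The Residency Index (RI) of a shark is

    RI = number of detection days / monitoring period (days),

where a detection day is a local calendar day with at least two
detections anywhere on the array and the monitoring period is the
expected tag battery life, truncated at the end of the study for tags
whose battery outlives it. RI ranges 0-1, low to high residency.

The Classification of Residency (CR) sorts sharks into four behavioural
categories from their detection timing:

* Passer-by - never detected after the first 30-day block ("Month")
  post tagging;
* Transient - re-detected after a gap longer than a Month but with
  fewer than three detection months in total;
* Pseudo-resident - three or more detection months, present for less
  than 30% of the detection period;
* Resident - three or more detection months, present for at least 30%
  of the detection period.

A "detection month" is a calendar month (year + month) containing at
least one detection day, which differs from the classifier's 30-day
"Month" block; both notions are implemented and named distinctly.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import StudyConfig
from .errors import MetadataError
from .io import SharkRecord


class Residency(str, enum.Enum):
    """Residency categories with their conventional display labels."""

    PASSER_BY = "Pass.-by"
    TRANSIENT = "Trans."
    PSEUDO_RESIDENT = "Ps.-res."
    RESIDENT = "Resident"


@dataclass(frozen=True)
class DetectionMetrics:
    """Per-shark detection tallies feeding RI and CR.

    ``detection_days`` (the actual calendar days) is populated when the
    metrics come from detection data; it may be left empty when metrics
    are reconstructed from a published summary table, in which case
    only the month-level classifier branch (resident / pseudo-resident)
    is exact.
    """

    tag_id: str
    n_detections: int
    n_detection_days: int
    detection_period_days: int  # tagging date -> last detection, date difference
    n_detection_months: int  # distinct calendar months holding a detection day
    monitoring_period_days: int
    detection_days: tuple = ()  # sorted local calendar days (pd.Timestamp)

    def __post_init__(self) -> None:
        if self.detection_days and len(self.detection_days) != self.n_detection_days:
            raise MetadataError(
                f"tag {self.tag_id}: detection_days length contradicts n_detection_days"
            )

    def inconsistencies(self) -> list[str]:
        """Flag tallies that contradict each other (bad source tables)."""
        issues = []
        if self.n_detection_days > self.detection_period_days + 1:
            issues.append("more detection days than the detection period allows")
        if self.n_detection_days > self.monitoring_period_days:
            issues.append("more detection days than the monitoring period allows")
        if self.n_detection_months > self.n_detection_days:
            issues.append("more detection months than detection days allow")
        if self.n_detection_days >= 1 and self.n_detection_months < 1:
            issues.append("detection days without a detection month")
        return issues

    @classmethod
    def from_summary_row(cls, row) -> "DetectionMetrics":
        """Rebuild metrics from a per-shark summary table row.

        Expects the column names used by
        :func:`reeftrace.datasets.load_cayman_summary`; the day-level
        detail is unavailable in a summary table and stays empty.
        """
        return cls(
            tag_id=str(row["tag_id"]),
            n_detections=int(row["n_detections"]),
            n_detection_days=int(row["n_detection_days"]),
            detection_period_days=int(row["detection_period_days"]),
            n_detection_months=int(row["n_detection_months"]),
            monitoring_period_days=int(row["tag_life_days"]),
        )


@dataclass(frozen=True)
class ResidencyResult:
    tag_id: str
    ri: float
    cr: Optional[Residency]
    presence_pct: Optional[float]


def monitoring_period(shark: SharkRecord, config: StudyConfig) -> int:
    """Expected tag life in days, truncated at the end of the study."""
    to_end = (config.study_end - shark.tagging_date).days
    period = min(shark.tag_life_days, to_end)
    if period <= 0:
        raise MetadataError(
            f"tag {shark.tag_id}: non-positive monitoring period "
            f"(tagged {shark.tagging_date}, study ends {config.study_end})"
        )
    return period


def detection_metrics(
    dets: pd.DataFrame, shark: SharkRecord, config: StudyConfig
) -> DetectionMetrics:
    """Compute detection tallies for one shark.

    ``dets`` holds the pre-processed detections of this tag only.
    Detections stamped before the tagging date are implausible and are
    excluded with a warning.
    """
    tagging = pd.Timestamp(shark.tagging_date)
    if not dets.empty:
        early = dets["date"] < tagging
        if early.any():
            warnings.warn(
                f"tag {shark.tag_id}: {int(early.sum())} detections before "
                "tagging date excluded",
                stacklevel=2,
            )
            dets = dets[~early]
    mon = monitoring_period(shark, config)
    if dets.empty:
        return DetectionMetrics(shark.tag_id, 0, 0, 0, 0, mon)

    per_day = dets.groupby("date").size()
    days = tuple(sorted(per_day.index[per_day >= 2]))
    months = {(d.year, d.month) for d in days}
    period = int((dets["date"].max() - tagging).days)
    return DetectionMetrics(
        tag_id=shark.tag_id,
        n_detections=int(len(dets)),
        n_detection_days=len(days),
        detection_period_days=period,
        n_detection_months=len(months),
        monitoring_period_days=mon,
        detection_days=days,
    )


def residency_index(m: DetectionMetrics) -> float:
    """RI = detection days / monitoring period, at full precision."""
    if m.monitoring_period_days <= 0:
        raise MetadataError(f"tag {m.tag_id}: monitoring period must be positive")
    return m.n_detection_days / m.monitoring_period_days


def classify_residency(
    m: DetectionMetrics, dets: pd.DataFrame, config: StudyConfig, shark: SharkRecord
) -> ResidencyResult:
    """Apply the four-category residency classifier.

    Sharks with no detection days cannot be classified and are returned
    with ``cr=None`` (absent from the residency analysis). A presence
    percentage exactly at the threshold classifies as Resident (the
    published criteria leave equality unassigned; >= is used here).
    """
    ri = residency_index(m)
    if m.n_detection_days == 0:
        return ResidencyResult(m.tag_id, ri, None, None)

    days = pd.DatetimeIndex(m.detection_days)
    tagging = pd.Timestamp(shark.tagging_date)
    first_block_end = tagging + pd.Timedelta(days=config.month_block_days)

    if m.n_detection_months >= 3:
        if m.detection_period_days <= 0:
            # all detection days on the tagging day yet >= 3 months is impossible
            raise MetadataError(f"tag {m.tag_id}: inconsistent metrics")
        presence = m.n_detection_days / m.detection_period_days * 100.0
        cr = (
            Residency.RESIDENT
            if presence >= config.presence_threshold_pct
            else Residency.PSEUDO_RESIDENT
        )
        return ResidencyResult(m.tag_id, ri, cr, presence)

    presence = (
        m.n_detection_days / m.detection_period_days * 100.0
        if m.detection_period_days > 0
        else None
    )
    if (days > first_block_end).any():
        return ResidencyResult(m.tag_id, ri, Residency.TRANSIENT, presence)
    return ResidencyResult(m.tag_id, ri, Residency.PASSER_BY, presence)


def cohort_summary(
    sharks: pd.DataFrame,
    metrics: Iterable[DetectionMetrics],
) -> dict:
    """Cohort-level means, standard errors and ranges.

    Detection counts, detection days and detection periods are averaged
    over the full tagged cohort with zeros imputed for never-detected
    sharks; RI is averaged over detected sharks only (tags without
    detections carry no RI).
    """
    metrics = list(metrics)
    if len(sharks) == 0:
        raise MetadataError("empty cohort")
    n_tagged = len(sharks)
    by_tag = {m.tag_id: m for m in metrics}
    unknown = set(by_tag) - set(sharks["tag_id"].astype(str))
    if unknown:
        raise MetadataError(f"metrics for tags not in cohort: {sorted(unknown)}")

    def col(fn):
        vals = np.zeros(n_tagged)
        for i, tag in enumerate(sharks["tag_id"].astype(str)):
            m = by_tag.get(tag)
            vals[i] = fn(m) if m is not None else 0.0
        return vals

    detections = col(lambda m: m.n_detections)
    days = col(lambda m: m.n_detection_days)
    periods = col(lambda m: m.detection_period_days)
    detected = [m for m in metrics if m.n_detections > 0]
    ri = np.array([residency_index(m) for m in detected])

    return {
        "n_tagged": n_tagged,
        "n_detected": len(detected),
        "n_detections": _describe(detections),
        "n_detection_days": _describe(days),
        "detection_period_days": _describe(periods),
        "ri": _describe(ri) if len(ri) else None,
    }


def _describe(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    out = {
        "mean": float(values.mean()),
        "min": float(values.min()),
        "max": float(values.max()),
        "n": int(len(values)),
    }
    out["se"] = (
        float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else None
    )
    return out
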