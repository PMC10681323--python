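"""End-to-end pipeline: files in, summary tables and networks out.

Stages: load -> resolve serials to stations and local time -> drop
excluded stations (six-month rule) -> remove single detections ->
per-shark metrics (RI, residency class, MLD, station usage / SFI) ->
station utilization, monthly activity -> subset movement networks
(sex, maturity, season, diel). Deterministic for a fixed config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import networks as net
from . import preprocess as prep
from . import residency as res
from . import space_use as su
from .config import StudyConfig
from .errors import ReeftraceError
from .io import (
    DEFAULT_DIALECT,
    DetectionDialect,
    SharkRecord,
    load_deployments,
    load_detections,
    load_sharks,
    load_stations,
)

SUBSET_SPECS = {
    "female": ("sex", "F"),
    "male": ("sex", "M"),
    "immature": ("maturity", "IM"),
    "mature": ("maturity", "M"),
    "summer": ("season", "summer"),
    "winter": ("season", "winter"),
    "day": ("diel", "day"),
    "night": ("diel", "night"),
}


@dataclass
class PipelineResult:
    shark_summary: pd.DataFrame
    station_utilization: pd.DataFrame
    monthly_activity: pd.DataFrame
    cohort: dict
    networks: dict  # label -> MovementNetwork
    preprocessing: dict

    def write(self, out_dir: str | Path, stations: Optional[pd.DataFrame] = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.shark_summary.to_csv(out / "shark_summary.csv", index=False)
        self.station_utilization.to_csv(out / "station_utilization.csv", index=False)
        self.monthly_activity.to_csv(out / "monthly_activity.csv", index=False)
        report = {
            "cohort": self.cohort,
            "preprocessing": self.preprocessing,
            "networks": {k: v.summary() for k, v in sorted(self.networks.items())},
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        for label, network in sorted(self.networks.items()):
            net.export_network(network, out / f"network_{label}", stations)


def run_pipeline(
    detections_path: str | Path,
    stations_path: str | Path,
    deployments_path: str | Path,
    sharks_path: str | Path,
    config: StudyConfig,
    out_dir: Optional[str | Path] = None,
    dialect: DetectionDialect = DEFAULT_DIALECT,
) -> PipelineResult:
    """Run every stage on the four input tables.

    Stage failures propagate with a stage label prefixed to the error
    message. Returns all result tables; also writes them under
    ``out_dir`` when given.
    """
    try:
        raw, issues = load_detections(detections_path, dialect, config.bad_row_tolerance)
        stations = load_stations(stations_path)
        deployments = load_deployments(deployments_path)
        sharks = load_sharks(sharks_path)
    except ReeftraceError as exc:
        raise type(exc)(f"[load] {exc}") from exc

    try:
        dets, report = prep.resolve_stations(raw, deployments, stations, config)
        working = prep.station_working_days(deployments, config)
        dets, n_excluded = prep.filter_excluded_stations(dets, working)
        dets = prep.remove_single_detections(dets)
    except ReeftraceError as exc:
        raise type(exc)(f"[preprocess] {exc}") from exc

    preprocessing = {
        "n_raw_rows": report.n_input,
        "n_malformed_rows": len(issues),
        "n_duplicates_dropped": report.n_duplicates,
        "n_unresolved_dropped": report.n_unresolved,
        "n_excluded_station_dropped": int(n_excluded),
        "n_detections_final": int(len(dets)),
        "n_stations_excluded": int(working["excluded"].sum()),
    }

    summary_rows = []
    metrics_all = []
    for _, row in sharks.sort_values("tag_id").iterrows():
        shark = SharkRecord.from_row(row)
        mine = dets[dets["tag_id"] == shark.tag_id]
        m = res.detection_metrics(mine, shark, config)
        metrics_all.append(m)
        entry = {
            "tag_id": shark.tag_id,
            "sex": shark.sex,
            "maturity": shark.maturity,
            "tl_cm": shark.tl_cm,
            "tagging_year": shark.tagging_date.year,
            "tagging_island": shark.tagging_island,
            "monitoring_period_days": m.monitoring_period_days,
            "n_detections": m.n_detections,
            "n_detection_days": m.n_detection_days,
            "detection_period_days": m.detection_period_days if m.n_detections else 0,
            "n_detection_months": m.n_detection_months,
            "ri": np.nan,
            "cr": None,
            "mld_km": np.nan,
            "n_receivers": 0,
            "n_islands": 0,
            "primary_sfi_pct": np.nan,
            "primary_station": None,
        }
        if m.n_detections > 0:
            classed = res.classify_residency(m, mine, config, shark)
            entry["ri"] = classed.ri
            entry["cr"] = classed.cr.value if classed.cr else None
            mld = su.minimum_linear_displacement(mine, shark, stations)
            entry["mld_km"] = mld.mld_km
            entry["n_islands"] = mld.n_islands
            entry["n_receivers"] = int(mine["station_id"].nunique())
            if m.n_detection_days > 0:
                usage = su.station_usage(mine, config)
                entry["primary_sfi_pct"] = float(usage["sfi"].iloc[0])
                entry["primary_station"] = usage["station_id"].iloc[0]
        summary_rows.append(entry)
    shark_summary = pd.DataFrame(summary_rows)

    cohort = res.cohort_summary(sharks, metrics_all)
    utilization = su.utilization_index(dets, working, config)
    month_days = prep.station_month_working_days(deployments, config)
    activity = su.activity_index(dets, month_days)

    dets_nets = net.assign_period(dets, config)
    sex_map = sharks.set_index("tag_id")["sex"]
    mat_map = sharks.set_index("tag_id")["maturity"]
    dets_nets["sex"] = dets_nets["tag_id"].map(sex_map)
    dets_nets["maturity"] = dets_nets["tag_id"].map(mat_map)
    node_universe = sorted(working.loc[~working["excluded"], "station_id"])
    networks = {
        label: net.build_network(
            dets_nets, node_universe, subset=dets_nets[col] == value, label=label
        )
        for label, (col, value) in SUBSET_SPECS.items()
    }
    networks["all"] = net.build_network(dets_nets, node_universe, label="all")

    result = PipelineResult(
        shark_summary=shark_summary,
        station_utilization=utilization,
        monthly_activity=activity,
        cohort=cohort,
        networks=networks,
        preprocessing=preprocessing,
    )
    if out_dir is not None:
        result.write(out_dir, stations)
    return result
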