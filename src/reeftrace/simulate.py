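"""Agent-based generator of acoustic detection logs with known truth.

The generator emulates a multi-island receiver array monitoring tagged
reef sharks: stations sit on island-perimeter circles, each station
carries a receiver whose deployment calendar may contain outage
windows, and each shark follows one of four behavioural archetypes
(resident, pseudo-resident, transient, passer-by) mirroring the
residency classifier's categories.

Movement is a daily-resolution station choice: on a "present" day the
shark lingers near one station (its home site with high probability, a
same-island alternative otherwise) for a residence window, during
which the tag's transmissions - exponentially spaced around a 90 s
mean - are detected independently with a fixed in-range probability.
Occasional excursions relocate the shark to another island for the
day; by default these occur in summer only, reproducing the seasonal
inter-island movement pattern of the study system. The daily
resolution is sufficient because every downstream metric is computed
at day resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import StudyConfig
from .errors import ConfigurationError
from .residency import Residency

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class IslandSpec:
    name: str
    lat: float
    lon: float
    n_stations: int
    radius_km: float = 5.0


#: Archetype proportions observed among detected sharks in the Cayman
#: study system (23 passers-by, 3 transients, 6 pseudo-residents and 7
#: residents of 39 detected individuals).
ARCHETYPE_MIX_DEFAULT = {
    Residency.PASSER_BY: 23 / 39,
    Residency.TRANSIENT: 3 / 39,
    Residency.PSEUDO_RESIDENT: 6 / 39,
    Residency.RESIDENT: 7 / 39,
}


@dataclass
class SimConfig:
    """Scenario parameters; defaults emulate the Cayman study conditions."""

    islands: tuple = (IslandSpec("GC", 19.3222, -81.2409, 23, 10.0),)
    n_sharks: int = 10
    archetype_mix: dict = field(default_factory=lambda: dict(ARCHETYPE_MIX_DEFAULT))
    mean_transmission_delay_s: float = 90.0
    detection_radius_km: float = 0.3
    detection_prob_in_range: float = 0.5
    swim_speed_bl_per_s: float = 0.6
    tl_range_cm: tuple = (76.0, 196.0)
    tag_life_days: dict = field(default_factory=lambda: {"V9": 480, "V16": 1262})
    prop_female: float = 0.5
    prop_mature: float = 0.5
    resident_presence_range: tuple = (0.4, 0.7)
    pseudo_presence_range: tuple = (0.06, 0.15)
    summer_presence_multiplier: float = 1.0  # seasonal forcing of presence
    summer_interisland_rate: float = 0.01  # daily excursion probability, Apr-Sep
    winter_interisland_rate: float = 0.0  # study system: no winter crossings
    receiver_outage_rate: float = 0.0  # expected downtime fraction per station
    mean_outage_days: float = 14.0
    residence_window_hours: float = 1.0
    home_bias: float = 0.75
    study_start: date = date(2015, 1, 1)
    study_span_days: int = 730
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.archetype_mix.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("archetype_mix proportions must sum to 1")
        if self.mean_transmission_delay_s <= 0 or self.residence_window_hours <= 0:
            raise ConfigurationError("delays and residence windows must be positive")
        if self.residence_window_hours > 8:
            raise ConfigurationError(
                "residence_window_hours must be <= 8 so a window never crosses "
                "a local midnight"
            )
        if not 0 < self.detection_prob_in_range <= 1:
            raise ConfigurationError("detection_prob_in_range must be in (0, 1]")
        if any(r < 0 for r in (self.summer_interisland_rate, self.winter_interisland_rate,
                               self.receiver_outage_rate)):
            raise ConfigurationError("rates must be non-negative")
        if sum(i.n_stations for i in self.islands) == 0:
            raise ConfigurationError("scenario needs at least one station")

    @property
    def study_end(self) -> date:
        return self.study_start + timedelta(days=self.study_span_days)

    def study_config(self, **overrides) -> StudyConfig:
        """A matching analysis configuration for this scenario."""
        kwargs = dict(
            study_start=self.study_start,
            study_end=self.study_end,
            rng_seed=self.seed,
        )
        kwargs.update(overrides)
        return StudyConfig(**kwargs)


def cayman_like(n_sharks: int = 66, span_days: int = 1095, seed: int = 0, **kw) -> SimConfig:
    """Three-island, 57-station scenario shaped like the Cayman array."""
    islands = (
        IslandSpec("GC", 19.3222, -81.2409, 23, 12.0),
        IslandSpec("LC", 19.6897, -80.0367, 28, 6.0),
        IslandSpec("CB", 19.7235, -79.8017, 8, 5.0),
    )
    return SimConfig(islands=islands, n_sharks=n_sharks, study_span_days=span_days,
                     seed=seed, **kw)


def minimal(n_sharks: int = 5, seed: int = 0, **kw) -> SimConfig:
    """Single-island, 8-station scenario for quick end-to-end runs."""
    islands = (IslandSpec("ISL", 19.5, -80.5, 8, 4.0),)
    return SimConfig(islands=islands, n_sharks=n_sharks, study_span_days=400,
                     seed=seed, **kw)


@dataclass
class SimOutput:
    """Synthetic detection log plus the tables and ground truth behind it."""

    detections: pd.DataFrame  # receiver-export dialect columns
    stations: pd.DataFrame
    deployments: pd.DataFrame
    sharks: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def to_csv(self, out_dir: str | Path) -> dict:
        """Write the four pipeline inputs, the ground truth and a
        matching analysis config file."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("detections", self.detections),
            ("stations", self.stations),
            ("deployments", self.deployments),
            ("sharks", self.sharks),
            ("truth", self.truth),
        ]:
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        config_path = out_dir / "config.yml"
        with open(config_path, "w") as fh:
            yaml.safe_dump(
                {
                    "study_start": str(self.config.study_start),
                    "study_end": str(self.config.study_end),
                    "rng_seed": int(self.config.seed),
                },
                fh,
            )
        paths["config"] = config_path
        return paths


def crossing_time_s(tl_cm: float, distance_m: float, speed_bl_per_s: float = 0.6) -> float:
    """Seconds a shark needs to swim a distance at a body-length speed."""
    if tl_cm <= 0 or distance_m <= 0 or speed_bl_per_s <= 0:
        raise ConfigurationError("crossing_time_s requires positive inputs")
    return distance_m / (speed_bl_per_s * tl_cm / 100.0)


def generate_array(cfg: SimConfig, rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place stations on island perimeters and build deployment calendars.

    Station coordinates are evenly spaced on a circle of the island's
    perimeter radius. Each station gets one receiver serial; outage
    windows (mean length ``mean_outage_days``) are removed from its
    deployment history until the expected downtime fraction matches
    ``receiver_outage_rate``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    start = pd.Timestamp(cfg.study_start)
    span = cfg.study_span_days

    st_rows, dep_rows = [], []
    serial = 123000
    for isl in cfg.islands:
        if isl.n_stations <= 0:
            raise ConfigurationError(f"island {isl.name}: needs at least one station")
        theta = 2 * np.pi * np.arange(isl.n_stations) / isl.n_stations
        dlat = isl.radius_km / 111.32 * np.cos(theta)
        dlon = isl.radius_km / (111.32 * np.cos(np.radians(isl.lat))) * np.sin(theta)
        for k in range(isl.n_stations):
            sid = f"{isl.name}-{k + 1:02d}"
            st_rows.append(
                {
                    "station_id": sid,
                    "island": isl.name,
                    "lat": isl.lat + dlat[k],
                    "lon": isl.lon + dlon[k],
                }
            )
            up = np.ones(span, dtype=bool)
            if cfg.receiver_outage_rate > 0:
                n_windows = rng.poisson(
                    cfg.receiver_outage_rate * span / cfg.mean_outage_days
                )
                for _ in range(n_windows):
                    length = 1 + rng.geometric(1.0 / cfg.mean_outage_days)
                    s = rng.integers(0, span)
                    up[s : min(span, s + length)] = False
            # contiguous up-runs become deployment intervals
            edges = np.flatnonzero(np.diff(np.concatenate(([0], up.view(np.int8), [0]))))
            for s, e in zip(edges[::2], edges[1::2]):
                dep_rows.append(
                    {
                        "receiver_serial": str(serial),
                        "station_id": sid,
                        "start_date": start + pd.Timedelta(days=int(s)),
                        "end_date": start + pd.Timedelta(days=int(e) - 1),
                    }
                )
            serial += 1
    stations = pd.DataFrame(st_rows)
    deployments = pd.DataFrame(dep_rows)
    return stations, deployments


def _presence_and_truth(cfg: SimConfig, rng, archetype, t0: int, mon: int):
    """Present-day boolean array over the monitoring window + truth fields."""
    present = np.zeros(mon, dtype=bool)
    truth = {"daily_presence_prob": np.nan, "departure_day": np.nan}

    def seasonal(q: float) -> np.ndarray:
        qvec = np.full(mon, q)
        if cfg.summer_presence_multiplier != 1.0:
            months = (
                pd.Timestamp(cfg.study_start)
                + pd.to_timedelta(t0 + np.arange(mon), unit="D")
            ).month
            qvec[np.isin(months, [4, 5, 6, 7, 8, 9])] = min(
                1.0, q * cfg.summer_presence_multiplier
            )
        return qvec

    if archetype is Residency.RESIDENT:
        q = rng.uniform(*cfg.resident_presence_range)
        present[:] = rng.random(mon) < seasonal(q)
        truth["daily_presence_prob"] = q
    elif archetype is Residency.PSEUDO_RESIDENT:
        q = rng.uniform(*cfg.pseudo_presence_range)
        present[:] = rng.random(mon) < seasonal(q)
        truth["daily_presence_prob"] = q
    elif archetype is Residency.PASSER_BY:
        dep = int(rng.integers(5, 26))
        horizon = min(dep, mon)
        present[:horizon] = rng.random(horizon) < 0.8
        truth.update(daily_presence_prob=0.8, departure_day=dep)
    elif archetype is Residency.TRANSIENT:
        # two detection bursts confined to two calendar months separated
        # by > 30 silent days, so total detection months stay below 3
        d0 = pd.Timestamp(cfg.study_start) + pd.Timedelta(days=t0)
        month_end = (d0 + pd.offsets.MonthEnd(0)).normalize()
        b1_len = min(5, (month_end - d0).days + 1, mon)
        present[:b1_len] = rng.random(b1_len) < 0.9
        b2_month = (d0 + pd.offsets.MonthBegin(2)).normalize()
        b2_off = (b2_month + pd.Timedelta(days=4) - d0).days
        for k in range(b2_off, min(b2_off + 5, mon)):
            if k >= 0:
                present[k] = rng.random() < 0.9
        truth["daily_presence_prob"] = 0.9
    else:  # pragma: no cover - guarded by SimConfig validation
        raise ConfigurationError(f"unknown archetype {archetype}")
    return present, truth


def simulate_sharks(cfg: SimConfig) -> SimOutput:
    """Run the full scenario: array, sharks, behaviour, detections."""
    rng = np.random.default_rng(cfg.seed)
    stations, deployments = generate_array(cfg, rng)
    span = cfg.study_span_days
    start = pd.Timestamp(cfg.study_start)

    # per-station working mask for dropping detections during outages
    st_index = {s: i for i, s in enumerate(stations["station_id"])}
    working = np.zeros((len(stations), span), dtype=bool)
    for _, dep in deployments.iterrows():
        a = (dep["start_date"] - start).days
        b = (dep["end_date"] - start).days
        working[st_index[dep["station_id"]], a : b + 1] = True

    by_island = {
        isl: grp["station_id"].tolist() for isl, grp in stations.groupby("island")
    }
    serial_of = (
        deployments.drop_duplicates("station_id")
        .set_index("station_id")["receiver_serial"]
        .to_dict()
    )
    island_names = list(by_island)
    coords = stations.set_index("station_id")

    archetypes = list(cfg.archetype_mix)
    probs = np.array([cfg.archetype_mix[a] for a in archetypes], dtype=float)

    mu = cfg.residence_window_hours * 3600.0 / cfg.mean_transmission_delay_s
    mu_detected = mu * cfg.detection_prob_in_range

    shark_rows, truth_rows, det_frames = [], [], []
    for i in range(cfg.n_sharks):
        tag = str(20000 + i)
        archetype = archetypes[rng.choice(len(archetypes), p=probs)]
        island = island_names[int(rng.integers(len(island_names)))]
        home = by_island[island][int(rng.integers(len(by_island[island])))]
        tl = float(rng.uniform(*cfg.tl_range_cm))
        tag_type = "V9" if tl < 110 else "V16"
        tag_life = int(cfg.tag_life_days[tag_type])
        t0 = int(rng.integers(0, max(1, span // 2)))
        mon = min(tag_life, span - t0)
        if mon <= 0:
            raise ConfigurationError("tagging date after study end")

        present, truth_extra = _presence_and_truth(cfg, rng, archetype, t0, mon)

        # station per present day: home-biased, same-island otherwise
        day_idx = np.flatnonzero(present) + t0
        n_days = len(day_idx)
        same_island = by_island[island]
        station_choice = np.where(
            rng.random(n_days) < cfg.home_bias,
            home,
            [same_island[j] for j in rng.integers(len(same_island), size=n_days)],
        ).astype(object)

        # summer-biased excursions to another island (long-stay archetypes)
        trip_months: set = set()
        if len(island_names) > 1 and archetype in (
            Residency.RESIDENT,
            Residency.PSEUDO_RESIDENT,
        ):
            months = (start + pd.to_timedelta(day_idx, unit="D")).month
            is_summer = np.isin(months, [4, 5, 6, 7, 8, 9])
            rate = np.where(
                is_summer, cfg.summer_interisland_rate, cfg.winter_interisland_rate
            )
            trips = rng.random(n_days) < rate
            others = [n for n in island_names if n != island]
            for j in np.flatnonzero(trips):
                other = others[int(rng.integers(len(others)))]
                station_choice[j] = by_island[other][
                    int(rng.integers(len(by_island[other])))
                ]
                trip_months.add(int(months[j]))

        # detections: Poisson-thinned transmissions inside a residence
        # window placed fully within one local day, so a present day
        # maps to exactly one local calendar day
        n_det = rng.poisson(mu_detected, size=n_days)
        st_rows_idx = np.array([st_index[s] for s in station_choice])
        n_det[~working[st_rows_idx, day_idx]] = 0
        keep = n_det > 0
        if keep.any():
            reps = n_det[keep]
            day_rep = np.repeat(day_idx[keep], reps)
            st_rep = np.repeat(station_choice[keep], reps)
            win_hi = max(23.75 - cfg.residence_window_hours, 0.25 + 1e-9)
            win_start = rng.uniform(0.25, win_hi, size=len(day_rep))
            local_s = (win_start + rng.uniform(0, cfg.residence_window_hours, size=len(day_rep))) * 3600.0
            ts_local = start + pd.to_timedelta(day_rep, unit="D") + pd.to_timedelta(
                np.round(local_s), unit="s"
            )
            ts_utc = ts_local + pd.Timedelta(hours=5)
            serials = [serial_of[s] for s in st_rep]
            det_frames.append(
                pd.DataFrame(
                    {
                        "Date and Time (UTC)": ts_utc.strftime("%Y-%m-%d %H:%M:%S"),
                        "Receiver": [f"VR2W-{s}" for s in serials],
                        "Transmitter": f"A69-1602-{tag}",
                    }
                )
            )

        home_pos = coords.loc[home]
        shark_rows.append(
            {
                "tag_id": tag,
                "sex": "F" if rng.random() < cfg.prop_female else "M",
                "maturity": "M" if rng.random() < cfg.prop_mature else "IM",
                "tl_cm": round(tl, 1),
                "tagging_date": (start + pd.Timedelta(days=t0)).date(),
                "tagging_lat": float(home_pos["lat"]),
                "tagging_lon": float(home_pos["lon"]),
                "island": island,
                "tag_type": tag_type,
                "tag_life_days": tag_life,
            }
        )
        truth_rows.append(
            {
                "tag_id": tag,
                "archetype": archetype.value,
                "home_station": home,
                "daily_presence_prob": truth_extra["daily_presence_prob"],
                "departure_day": truth_extra["departure_day"],
                "interisland_trip_months": ";".join(map(str, sorted(trip_months))),
            }
        )

    if det_frames:
        detections = pd.concat(det_frames, ignore_index=True)
        detections = detections.sort_values(
            ["Date and Time (UTC)", "Transmitter"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        detections = pd.DataFrame(
            columns=["Date and Time (UTC)", "Receiver", "Transmitter"]
        )

    deployments_out = deployments.copy()
    deployments_out["start_date"] = deployments_out["start_date"].dt.date
    deployments_out["end_date"] = deployments_out["end_date"].dt.date
    return SimOutput(
        detections=detections,
        stations=stations,
        deployments=deployments_out,
        sharks=pd.DataFrame(shark_rows),
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


def expected_ri(cfg: SimConfig, daily_presence_prob: float) -> float:
    """Analytic RI for a long-stay shark under the generator's model.

    A present day becomes a detection day when at least two of its
    Poisson-thinned transmissions are detected, so
    RI = q * P(N >= 2), N ~ Poisson(window / delay * p).
    """
    mu = (
        cfg.residence_window_hours
        * 3600.0
        / cfg.mean_transmission_delay_s
        * cfg.detection_prob_in_range
    )
    p_day = 1.0 - math.exp(-mu) * (1.0 + mu)
    return daily_presence_prob * p_day
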