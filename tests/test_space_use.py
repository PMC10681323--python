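"""Geodesics, site-fidelity indices, displacement and utilization."""

import itertools
import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reeftrace import (
    activity_index,
    great_circle_km,
    minimum_linear_displacement,
    station_usage,
    utilization_index,
)
from reeftrace.errors import ConfigurationError, MetadataError
from reeftrace.preprocess import station_working_days

from conftest import days_of_detections, make_detections
from test_residency import shark

EARTH_R = 6371.0
# independent reference: R geosphere::distHaversine on a 6371 km sphere,
# Grand Cayman centroid to Cayman Brac centroid
GC_CB_REFERENCE_KM = 157.2926
# same pair on the WGS84 ellipsoid (geosphere::distVincentyEllipsoid)
GC_CB_ELLIPSOID_KM = 157.4525


class TestGreatCircle:
    def test_identity(self):
        assert great_circle_km(19.3, -81.2, 19.3, -81.2) == 0.0

    def test_antipodal_closed_form(self):
        assert great_circle_km(0, 0, 0, 180) == pytest.approx(math.pi * EARTH_R, rel=1e-12)

    def test_island_centroids_match_reference(self):
        d = great_circle_km(19.3222, -81.2409, 19.7235, -79.8017)
        assert d == pytest.approx(GC_CB_REFERENCE_KM, rel=1e-4)
        assert d == pytest.approx(GC_CB_ELLIPSOID_KM, rel=2e-3)

    def test_invalid_coordinates(self):
        with pytest.raises(ConfigurationError):
            great_circle_km(95, 0, 0, 0)

    @given(
        st.lists(
            st.tuples(st.floats(-80, 80), st.floats(-179, 179)), min_size=3, max_size=3
        )
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_symmetry_and_triangle_inequality(self, pts):
        (a, b, c) = pts
        dab = great_circle_km(*a, *b)
        dba = great_circle_km(*b, *a)
        assert dab == pytest.approx(dba, abs=1e-9)
        dac = great_circle_km(*a, *c)
        dcb = great_circle_km(*c, *b)
        assert dab <= dac + dcb + 1e-6


class TestStationUsage:
    def test_single_station_shark(self, config):
        dets = days_of_detections("T1", [date(2015, 1, d) for d in (1, 2, 3)], per_day=2)
        usage = station_usage(dets, config)
        assert len(usage) == 1
        assert usage.loc[0, "di"] == pytest.approx(1.0)
        assert usage.loc[0, "sfi"] == pytest.approx(100.0)
        assert usage.loc[0, "rank"] == 1

    def test_product_rule(self, config):
        # station A: 2 of 4 detections and 1 of 2 detection days -> DI 0.25
        dets = pd.concat(
            [
                days_of_detections("T1", [date(2015, 1, 1)], per_day=2, station="A"),
                days_of_detections("T1", [date(2015, 1, 2)], per_day=2, station="B"),
            ]
        )
        usage = station_usage(dets, config).set_index("station_id")
        assert usage.loc["A", "di"] == pytest.approx(0.25)
        assert usage.loc["A", "sfi"] == pytest.approx(50.0)

    def test_three_station_hand_computation(self, config):
        dets = pd.concat(
            [
                days_of_detections("T1", [date(2015, 1, d) for d in (1, 2, 3)], per_day=4, station="A"),
                days_of_detections("T1", [date(2015, 2, d) for d in (1, 2)], per_day=2, station="B"),
                days_of_detections("T1", [date(2015, 3, 1)], per_day=2, station="C"),
            ]
        )
        # totals: 18 detections, 6 detection days
        # DI_A = (12/18)(3/6) = 1/3; DI_B = (4/18)(2/6) = 2/27; DI_C = (2/18)(1/6) = 1/54
        usage = station_usage(dets, config).set_index("station_id")
        di = usage["di"]
        assert di["A"] == pytest.approx(1 / 3)
        assert di["B"] == pytest.approx(2 / 27)
        assert di["C"] == pytest.approx(1 / 54)
        assert usage["sfi"].sum() == pytest.approx(100.0, abs=1e-9)
        assert list(usage.sort_values("rank").index) == ["A", "B", "C"]
        assert di.sum() <= 1.0

    def test_equal_di_tie_broken_by_station_id(self, config):
        dets = pd.concat(
            [
                days_of_detections("T1", [date(2015, 1, 1)], per_day=2, station="B"),
                days_of_detections("T1", [date(2015, 1, 2)], per_day=2, station="A"),
            ]
        )
        usage = station_usage(dets, config)
        assert list(usage["station_id"]) == ["A", "B"]
        assert usage["sfi"].tolist() == pytest.approx([50.0, 50.0])

    def test_no_detection_days_is_error(self, config):
        dets = days_of_detections("T1", [date(2015, 1, 1)], per_day=1)
        with pytest.raises(MetadataError):
            station_usage(dets, config)


def grid_stations(n, spacing_deg=0.05):
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        {
            "station_id": [f"S{i}" for i in range(n)],
            "island": "I1",
            "lat": 19.0 + rng.uniform(0, 1, n),
            "lon": -81.0 + rng.uniform(0, 1, n),
        }
    )


class TestMLD:
    def test_two_stations_known_distance(self):
        dphi = math.degrees(10.0 / EARTH_R)  # exactly 10 km along a meridian
        stations = pd.DataFrame(
            {
                "station_id": ["A", "B"],
                "island": ["I1", "I1"],
                "lat": [19.0, 19.0 + dphi],
                "lon": [-81.0, -81.0],
            }
        )
        dets = make_detections(
            [("2015-01-01 08:00", "A", "T1", "I1"), ("2015-01-02 08:00", "B", "T1", "I1")]
        )
        out = minimum_linear_displacement(dets, shark(), stations)
        assert out.mld_km == pytest.approx(10.6, abs=1e-9)
        assert not out.long_distance

    def test_single_station_uses_tagging_location(self):
        stations = pd.DataFrame(
            {"station_id": ["A"], "island": ["I1"], "lat": [19.3], "lon": [-81.2]}
        )
        s = shark(tagging_lat=19.3222, tagging_lon=-81.2409)
        dets = make_detections([("2015-01-01 08:00", "A", "T1", "I1")])
        out = minimum_linear_displacement(dets, s, stations)
        d = great_circle_km(19.3222, -81.2409, 19.3, -81.2)
        assert out.mld_km == pytest.approx(d + 0.3, abs=1e-9)
        assert out.endpoint_a == "tagging-location"

    def test_farthest_pair_matches_brute_force(self):
        stations = grid_stations(8)
        rows = [
            (f"2015-01-{d + 1:02d} 08:00", f"S{d}", "T1", "I1") for d in range(8)
        ]
        out = minimum_linear_displacement(make_detections(rows), shark(), stations)
        coords = stations.set_index("station_id")
        best = max(
            great_circle_km(
                coords.loc[a, "lat"], coords.loc[a, "lon"],
                coords.loc[b, "lat"], coords.loc[b, "lon"],
            )
            for a, b in itertools.combinations(coords.index, 2)
        )
        assert out.mld_km == pytest.approx(best + 0.6, abs=1e-9)

    def test_invariant_to_detection_multiplicity(self):
        stations = grid_stations(5)
        rows = [(f"2015-01-0{d + 1} 08:00", f"S{d}", "T1", "I1") for d in range(5)]
        dets = make_detections(rows)
        doubled = pd.concat([dets, dets]).reset_index(drop=True)
        a = minimum_linear_displacement(dets, shark(), stations)
        b = minimum_linear_displacement(doubled, shark(), stations)
        assert a.mld_km == b.mld_km and {a.endpoint_a, a.endpoint_b} == {b.endpoint_a, b.endpoint_b}

    def test_islands_counted_and_long_distance_flag(self, stations):
        rows = [
            ("2015-01-01 08:00", "A", "T1", "I1"),
            ("2015-02-01 08:00", "C", "T1", "I2"),
        ]
        out = minimum_linear_displacement(make_detections(rows), shark(), stations)
        assert out.n_islands == 2
        assert out.long_distance == (out.mld_km > 50)

    def test_no_detections_is_error(self, stations):
        with pytest.raises(MetadataError):
            minimum_linear_displacement(make_detections([]), shark(), stations)


class TestUtilization:
    def working(self, config, rows):
        deps = pd.DataFrame(
            rows, columns=["receiver_serial", "station_id", "start_date", "end_date"]
        ).assign(
            start_date=lambda d: pd.to_datetime(d["start_date"]),
            end_date=lambda d: pd.to_datetime(d["end_date"]),
        )
        return station_working_days(deps, config)

    def test_station_without_sharks_has_zero_ui(self, config):
        working = self.working(
            config,
            [("S1", "A", "2015-01-01", "2016-12-31"), ("S2", "B", "2015-01-01", "2016-12-31")],
        )
        dets = days_of_detections("T1", [date(2015, 1, 1), date(2015, 1, 2)], station="A")
        out = utilization_index(dets, working, config).set_index("station_id")
        assert out.loc["B", "ui"] == 0.0
        assert out.loc["A", "ui"] > 0

    def test_single_station_formula_trace(self, config):
        working = self.working(config, [("S1", "A", "2015-01-01", "2016-12-31")])
        days = [date(2015, 1, 1) + pd.Timedelta(days=i) for i in range(10)]
        dets = days_of_detections("T1", days, station="A")
        out = utilization_index(dets, working, config)
        w = out.loc[0, "working_days"]
        # one shark of one: UI = 1 x (10/w)/10 = 1/w
        assert out.loc[0, "ui"] == pytest.approx(1.0 / w)

    def test_three_station_ranking(self, config):
        working = self.working(
            config,
            [
                ("S1", "A", "2015-01-01", "2016-12-31"),
                ("S2", "B", "2015-01-01", "2016-12-31"),
                ("S3", "C", "2015-01-01", "2016-12-31"),
            ],
        )
        dets = pd.concat(
            [
                days_of_detections("T1", [date(2015, 1, d) for d in range(1, 6)], station="A"),
                days_of_detections("T2", [date(2015, 1, d) for d in range(1, 4)], station="A"),
                days_of_detections("T2", [date(2015, 2, d) for d in range(1, 5)], station="B"),
                days_of_detections("T3", [date(2015, 3, 1)], station="C"),
            ]
        )
        out = utilization_index(dets, working, config).set_index("station_id")
        # A: 2 sharks, 8 station-days; B: 1 shark, 4; C: 1 shark, 1
        assert out.loc["A", "n_sharks"] == 2 and out.loc["A", "n_detection_days"] == 8
        assert out["ui"].idxmax() == "A"
        assert out.loc["B", "ui"] > out.loc["C", "ui"]


class TestActivityIndex:
    def month_days(self):
        return pd.Series(100, index=pd.RangeIndex(1, 13, name="month"))

    def test_month_without_detections_is_zero(self):
        dets = days_of_detections("T1", [date(2015, 1, 1), date(2015, 1, 2)])
        out = activity_index(dets, self.month_days(), n_detected_sharks=1).set_index("month")
        assert out.loc[7, "ai"] == 0.0
        assert out.loc[1, "ai"] == pytest.approx((2 / 100) * 1.0)

    def test_upper_bound_is_one(self):
        month_days = pd.Series(
            [31, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], index=pd.RangeIndex(1, 13, name="month")
        )
        days = [date(2015, 1, d) for d in range(1, 32)]
        dets = days_of_detections("T1", days)
        out = activity_index(dets, month_days, n_detected_sharks=1).set_index("month")
        assert out.loc[1, "ai"] == pytest.approx(1.0)

    def test_zero_working_days_month_is_absent(self):
        month_days = pd.Series(0, index=pd.RangeIndex(1, 13, name="month"))
        dets = days_of_detections("T1", [date(2015, 1, 1)])
        out = activity_index(dets, month_days, n_detected_sharks=1)
        assert out["ai"].isna().all()
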