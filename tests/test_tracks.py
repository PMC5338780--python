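"""Track cleaning, trip segmentation and spatial metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foragespec as fs
from foragespec.errors import InvalidInputError, UndefinedBearingError
from foragespec.tracks import EARTH_RADIUS_KM, haversine_km_vec, project_local_km

from conftest import COLONY, make_deployment


def law_of_cosines_km(a, b):
    """Independent spherical-law-of-cosines distance."""
    p1, l1, p2, l2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    c = (math.sin(p1) * math.sin(p2)
         + math.cos(p1) * math.cos(p2) * math.cos(l2 - l1))
    return EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, c)))


class TestHaversine:
    def test_identity(self):
        assert fs.haversine_km((0, 0), (0, 0)) == 0.0

    def test_one_degree_equator(self):
        assert fs.haversine_km((0, 0), (0, 1)) == pytest.approx(
            2 * math.pi * EARTH_RADIUS_KM / 360, abs=1e-4)

    @pytest.mark.parametrize("a,b", [
        ((0, 0), (1, 1)),
        ((-49.4, 70.4), (-49.2, 70.9)),
        ((60, -30), (59, -29)),
    ])
    def test_matches_law_of_cosines(self, a, b):
        assert fs.haversine_km(a, b) == pytest.approx(law_of_cosines_km(a, b), rel=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-80, 80), st.floats(-179, 179), st.floats(-80, 80),
           st.floats(-179, 179))
    def test_symmetric_nonnegative(self, la1, lo1, la2, lo2):
        d1 = fs.haversine_km((la1, lo1), (la2, lo2))
        d2 = fs.haversine_km((la2, lo2), (la1, lo1))
        assert d1 == pytest.approx(d2) and d1 >= 0

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            fs.haversine_km((float("nan"), 0), (0, 0))


class TestBearing:
    @pytest.mark.parametrize("b,expected", [
        ((0, 1), 90.0), ((1, 0), 0.0), ((0, -1), -90.0),
    ])
    def test_cardinal_directions(self, b, expected):
        assert fs.initial_bearing_deg((0, 0), b) == pytest.approx(expected)

    def test_south_maps_to_180_not_minus(self):
        assert fs.initial_bearing_deg((1, 0), (0, 0)) == pytest.approx(180.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(UndefinedBearingError):
            fs.initial_bearing_deg((1, 2), (1, 2))


class TestSpeedFilter:
    def test_displaced_middle_fix_removed(self):
        # 5 km jump in 60 s is ~83 m/s, far above the 18 m/s threshold
        dep = make_deployment([(0, 0), (5, 0), (0.05, 0)])
        out = fs.speed_filter(dep, vmax_mps=18.0)
        assert len(out.fixes) == 2
        assert out.fixes["lon"].iloc[1] == dep.fixes["lon"].iloc[2]

    def test_stationary_unchanged(self):
        dep = make_deployment([(0, 0)] * 4)
        assert len(fs.speed_filter(dep).fixes) == 4

    def test_infinite_threshold_noop(self):
        dep = make_deployment([(0, 0), (5, 0), (50, 0)])
        assert len(fs.speed_filter(dep, vmax_mps=math.inf).fixes) == 3

    def test_idempotent(self, small_population):
        _, deployments, *_ = small_population
        for dep in deployments:
            once = fs.speed_filter(dep)
            twice = fs.speed_filter(once)
            pd.testing.assert_frame_equal(once.fixes, twice.fixes)


class TestSegmentTrips:
    def test_two_excursions_with_colony_visit(self):
        path = ([(0, 0)] + [(i, 0) for i in (1, 2, 3, 4, 5, 4, 3, 2, 1)] + [(0, 0)]
                + [(0, i) for i in (1, 2, 3, 4, 5, 4, 3, 2, 1)] + [(0, 0)])
        trips = fs.segment_trips(make_deployment(path))
        assert [t.trip_index for t in trips] == [1, 2]
        # each trip is padded by the bounding at-colony fixes
        for t in trips:
            x, y = project_local_km(t.fixes["lat"], t.fixes["lon"], COLONY)
            assert math.hypot(x[0], y[0]) < 0.2 and math.hypot(x[-1], y[-1]) < 0.2

    def test_never_leaving_radius(self):
        dep = make_deployment([(0.01, 0.01)] * 6)
        assert fs.segment_trips(dep) == []

    def test_short_excursion_dropped(self):
        # 5 minutes away from the colony with a 10-minute minimum
        dep = make_deployment([(0, 0), (2, 0), (2.1, 0), (2, 0), (0, 0)], dt_s=75)
        assert fs.segment_trips(dep, min_duration_min=10) == []

    def test_recovers_simulated_trip_counts(self, small_population):
        _, deployments, _, _, _, truth = small_population
        for dep in deployments:
            n = len(fs.segment_trips(fs.speed_filter(dep)))
            expected = truth.trip_counts.query(
                "individual_id == @dep.individual_id and stage == @dep.stage"
            )["n_trips"].iloc[0]
            assert n == expected


class TestInterpolate:
    def test_two_fixes_ten_seconds(self):
        dep = make_deployment([(0, 0), (1, 0)], dt_s=10)
        tr = fs.Trip("B00", "chick_rearing", 1, dep.fixes)
        out = fs.interpolate_trip(tr, dt_s=1.0)
        assert len(out.fixes) == 11
        assert np.allclose(np.diff(out.fixes["lon"]), np.diff(out.fixes["lon"])[0])

    def test_idempotent_at_native_cadence(self):
        dep = make_deployment([(0, 0), (0.5, 0), (1, 0)], dt_s=1)
        tr = fs.Trip("B00", "chick_rearing", 1, dep.fixes)
        out = fs.interpolate_trip(tr, dt_s=1.0)
        pd.testing.assert_series_equal(out.fixes["lat"], tr.fixes["lat"])

    def test_midpoint_linearity(self):
        fixes = pd.DataFrame({
            "time": pd.to_datetime(["2015-01-01T00:00:00", "2015-01-01T00:00:10"]),
            "lat": [0.0, 0.0], "lon": [0.0, 0.002]})
        out = fs.interpolate_trip(fs.Trip("b", "s", 1, fixes), dt_s=5.0)
        assert out.fixes["lon"].iloc[1] == pytest.approx(0.001)


class TestTripMetrics:
    def test_out_and_back_east(self):
        path = [(0, 0)] + [(i, 0) for i in range(1, 11)] + \
               [(i, 0) for i in range(9, -1, -1)]
        tr = fs.Trip("B00", "chick_rearing", 1, make_deployment(path).fixes)
        tr = fs.trip_metrics(tr, COLONY)
        # planar offsets along a parallel differ from great-circle distance by
        # ~0.1% at this latitude and range
        assert tr.max_distance_km == pytest.approx(10.0, rel=3e-3)
        assert tr.total_distance_km == pytest.approx(20.0, rel=3e-3)
        assert tr.heading_deg == pytest.approx(90.0, abs=0.5)
        assert tr.duration_h == pytest.approx(20 * 60 / 3600)

    def test_single_segment(self):
        dep = make_deployment([(0, 0), (3, 4)])
        tr = fs.trip_metrics(fs.Trip("b", "s", 1, dep.fixes), COLONY)
        seg = fs.haversine_km((dep.fixes["lat"][0], dep.fixes["lon"][0]),
                              (dep.fixes["lat"][1], dep.fixes["lon"][1]))
        assert tr.total_distance_km == pytest.approx(seg)

    def test_max_bounded_by_total(self, small_population):
        _, deployments, *_ = small_population
        for dep in deployments:
            for tr in fs.segment_trips(fs.speed_filter(dep)):
                tr = fs.trip_metrics(tr, dep.colony)
                assert tr.max_distance_km <= tr.total_distance_km + 1e-9
                lat = tr.fixes["lat"].to_numpy()
                lon = tr.fixes["lon"].to_numpy()
                chord = fs.haversine_km((lat[0], lon[0]), (lat[-1], lon[-1]))
                assert tr.total_distance_km >= chord - 1e-9


class TestRasterize:
    def _trip(self, offsets):
        return fs.Trip("B00", "chick_rearing", 1, make_deployment(offsets).fixes)

    def test_colony_point_single_cell(self):
        assert len(fs.rasterize_trip(self._trip([(0, 0), (0, 0)]), COLONY)) == 1

    def test_east_transect_cell_count(self):
        # positions every 0.5 km from 0.25 to 3.25 km east -> x floors 0,0,1,1,2,2,3
        tr = self._trip([(0.25 + i * 0.5, 0.0) for i in range(7)])
        assert len(fs.rasterize_trip(tr, COLONY, cell_km=1.0)) == 4

    def test_refinement_monotone(self, small_population):
        _, deployments, *_ = small_population
        for dep in deployments[:2]:
            for tr in fs.segment_trips(fs.speed_filter(dep)):
                n_fine = len(fs.rasterize_trip(tr, dep.colony, 0.5))
                n_1 = len(fs.rasterize_trip(tr, dep.colony, 1.0))
                n_2 = len(fs.rasterize_trip(tr, dep.colony, 2.0))
                assert n_fine >= n_1 >= n_2

    def test_invalid_cell_size(self):
        with pytest.raises(InvalidInputError):
            fs.rasterize_trip(self._trip([(0, 0), (1, 1)]), COLONY, cell_km=0.0)
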