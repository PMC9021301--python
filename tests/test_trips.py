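import numpy as np
import pytest

from wayfind.geo import (
    EARTH_RADIUS_M,
    METERS_PER_MILE,
    DegenerateTripError,
    GeoPoint,
    haversine_distance,
)
from wayfind.roads import Edge, RoadNetwork, Router
from wayfind.trips import (
    Trip,
    actual_optimal_distance_ratio,
    actual_optimal_time_ratio,
    compute_trip_metrics,
    detect_overspeeding,
    detect_speed_events,
    straightness,
)


def make_trip(lats, lons, speeds=None, t0=0.0, dt=30.0, driver="d0", trip="t0"):
    n = len(lats)
    if speeds is None:
        speeds = np.full(n, 30.0)
    return Trip(driver, trip, t0 + dt * np.arange(n), np.asarray(lats),
                np.asarray(lons), np.asarray(speeds))


def equator_lon(miles: float) -> float:
    """Longitude (degrees) lying the given number of miles east of the
    origin along the equator."""
    return np.degrees(miles * METERS_PER_MILE / EARTH_RADIUS_M)


class TestTripInvariants:
    def test_requires_two_breadcrumbs(self):
        with pytest.raises(DegenerateTripError):
            make_trip([0.0], [0.0])

    def test_strictly_increasing_timestamps(self):
        with pytest.raises(ValueError):
            Trip("d", "t", [0, 0], [0, 0.1], [0, 0.1], [10, 10])

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            make_trip([0, 0.1], [0, 0.1], speeds=[-1, 10])


class TestStraightness:
    def test_geodesic_path_is_one(self):
        t = make_trip([0, 0, 0], [0, 0.1, 0.2])
        s, loop = straightness(t)
        assert s == pytest.approx(1.0, abs=1e-12)
        assert not loop

    def test_right_angle_path(self):
        t = make_trip([0, 0, 0.1], [0, 0.1, 0.1])
        s, _ = straightness(t)
        # haversine oracle on the three pairwise distances
        a, b, c = GeoPoint(0, 0), GeoPoint(0, 0.1), GeoPoint(0.1, 0.1)
        want = haversine_distance(a, c) / (
            haversine_distance(a, b) + haversine_distance(b, c)
        )
        assert s == pytest.approx(want, rel=1e-12)
        assert s == pytest.approx(1 / np.sqrt(2), rel=1e-4)

    def test_out_and_back_loop_flagged_zero(self):
        t = make_trip([0, 0, 0], [0, 0.1, 0])
        s, loop = straightness(t)
        assert s == 0.0 and loop

    def test_time_translation_invariance(self):
        t1 = make_trip([0, 0, 0.1], [0, 0.1, 0.1], t0=0.0)
        t2 = make_trip([0, 0, 0.1], [0, 0.1, 0.1], t0=123456.0)
        assert straightness(t1) == straightness(t2)


def worked_example():
    """A 6-mile driven trip on a network whose optimal route between the
    endpoints is 4 miles (straight equatorial street)."""
    nodes = {0: GeoPoint(0.0, 0.0), 1: GeoPoint(0.0, equator_lon(4.0))}
    net = RoadNetwork(nodes, [Edge(0, 1, 4.0 * METERS_PER_MILE, 30.0)])
    # out-and-back zigzag along the street: 2.5 + 1.0 + 2.5 = 6 miles
    lons = [equator_lon(m) for m in (0.0, 2.5, 1.5, 4.0)]
    trip = make_trip([0.0, 0.0, 0.0, 0.0], lons)
    return trip, net


class TestActualOptimalRatios:
    def test_six_over_four_miles_is_one_point_five(self):
        trip, net = worked_example()
        assert actual_optimal_distance_ratio(trip, net) == pytest.approx(1.5, abs=1e-9)

    def test_trip_along_optimal_route_is_one(self, grid_net):
        router = Router(grid_net, criterion="time")
        r = router.route(0, 18)
        lats = [grid_net.nodes[n].lat for n in r.nodes]
        lons = [grid_net.nodes[n].lon for n in r.nodes]
        trip = make_trip(lats, lons)
        assert actual_optimal_distance_ratio(trip, grid_net, router) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_short_slow_street_beats_long_fast_highway_on_distance(self):
        # triangle: direct slow street 0-2 (1 km, 10 mph) vs highway
        # 0-1-2 (3 km total, 60 mph). Time-optimal is the highway, so a
        # trip down the short street has distance ratio < 1.
        nodes = {
            0: GeoPoint(0.0, 0.0),
            1: GeoPoint(0.012, 0.005),
            2: GeoPoint(0.0, 0.009),
        }
        edges = [
            Edge(0, 2, 1000.0, 10.0),
            Edge(0, 1, 1500.0, 60.0),
            Edge(1, 2, 1500.0, 60.0),
        ]
        net = RoadNetwork(nodes, edges)
        router = Router(net, criterion="time")
        opt = router.route(0, 2)
        assert opt.nodes == (0, 1, 2)  # quickest, not shortest
        trip = make_trip([0.0, 0.0], [0.0, 0.009])
        ratio = actual_optimal_distance_ratio(trip, net, router)
        assert ratio < 1.0

    def test_time_ratio_at_limit_is_one(self):
        trip, net = worked_example()
        # optimal duration: 4 miles at 30 mph; drive the 6-mile zigzag in
        # exactly that time scaled by 6/4 at the limit => ratio 6/4 over
        # distance but duration ratio = observed/optimal
        opt_dur = 4.0 * METERS_PER_MILE / (30 * 0.44704)
        t = make_trip(
            [0, 0, 0, 0],
            [equator_lon(m) for m in (0.0, 2.5, 1.5, 4.0)],
            dt=opt_dur / 3.0,
        )
        assert actual_optimal_time_ratio(t, net) == pytest.approx(1.0, rel=1e-9)

    def test_time_ratio_doubles_with_duration(self):
        trip, net = worked_example()
        opt_dur = 4.0 * METERS_PER_MILE / (30 * 0.44704)
        t = make_trip(
            [0, 0, 0, 0],
            [equator_lon(m) for m in (0.0, 2.5, 1.5, 4.0)],
            dt=2.0 * opt_dur / 3.0,
        )
        assert actual_optimal_time_ratio(t, net) == pytest.approx(2.0, rel=1e-9)


class TestSpeedEvents:
    def test_constant_speed_no_events(self):
        t = make_trip([0, 0, 0], [0, 0.1, 0.2], speeds=[30, 30, 30])
        assert detect_speed_events(t) == (0, 0)

    def test_brake_and_accel_counted_once_each(self):
        t = make_trip([0, 0, 0], [0, 0.1, 0.2], speeds=[40, 10, 40])
        assert detect_speed_events(t, 15, 15) == (1, 1)

    def test_infinite_thresholds_silence_everything(self):
        t = make_trip([0, 0, 0], [0, 0.1, 0.2], speeds=[60, 0, 60])
        assert detect_speed_events(t, np.inf, np.inf) == (0, 0)


class TestOverspeeding:
    def test_below_limits_everywhere(self, line_net):
        t = make_trip([0, 0, 0], [0, 0.009, 0.018], speeds=[20, 25, 29])
        assert detect_overspeeding(t, line_net) == (0, 0.0)

    def test_single_run_fraction(self, line_net):
        speeds = [20, 20, 20, 40, 40, 40, 20, 20, 20, 20]
        lons = np.linspace(0, 0.018, 10)
        t = make_trip(np.zeros(10), lons, speeds=speeds)
        ev, frac = detect_overspeeding(t, line_net)
        assert (ev, frac) == (1, pytest.approx(0.3))

    def test_alternating_pattern(self, line_net):
        speeds = [40, 20, 40, 20, 40, 20]
        lons = np.linspace(0, 0.018, 6)
        t = make_trip(np.zeros(6), lons, speeds=speeds)
        ev, frac = detect_overspeeding(t, line_net)
        assert (ev, frac) == (3, pytest.approx(0.5))

    def test_tolerance_shifts_threshold(self, line_net):
        t = make_trip([0, 0], [0, 0.018], speeds=[33, 33])
        assert detect_overspeeding(t, line_net, tolerance_mph=0.0)[0] == 1
        assert detect_overspeeding(t, line_net, tolerance_mph=5.0)[0] == 0


class TestComputeTripMetrics:
    def test_full_panel_consistency(self, line_net):
        t = make_trip([0, 0, 0], [0, 0.009, 0.018], speeds=[25, 40, 25])
        m = compute_trip_metrics(t, line_net)
        assert m.straightness == pytest.approx(1.0, abs=1e-9)
        assert m.actual_optimal_distance_ratio == pytest.approx(1.0, rel=1e-3)
        assert m.hard_brake_count == 0 and m.hard_accel_count == 0
        assert m.overspeed_event_count == 1
        assert m.distance_mi == pytest.approx(2000.0 / METERS_PER_MILE, rel=1e-3)

    def test_routing_failure_marks_ratios_missing(self):
        nodes = {0: GeoPoint(0, 0), 1: GeoPoint(0, 0.009), 2: GeoPoint(0, 5.0)}
        net = RoadNetwork(nodes, [Edge(0, 1, 1000.0, 30.0)])
        t = make_trip([0, 0], [0, 5.0])  # destination snaps to isolated node
        with pytest.warns(UserWarning, match="routing failed"):
            m = compute_trip_metrics(t, net)
        assert m.actual_optimal_distance_ratio is None
        assert m.actual_optimal_time_ratio is None
        assert m.straightness > 0
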