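"""Per-trip route-selection metrics from 30-second GPS breadcrumbs.

A trip is an ordered sequence of timestamped GPS fixes ("breadcrumbs"),
nominally one every 30 s, each carrying an instantaneous speed in mph.
From a trip and a road network this module computes:

* **straightness** — great-circle distance between trip endpoints divided
  by the driven path length; 1 means a perfectly direct route. Loop
  trips (identical endpoints) are assigned straightness 0 and flagged,
  so that driver-level medians remain computable.
* **actual–optimal distance ratio** — driven path length divided by the
  length of the *time*-optimal route between the snapped endpoints (the
  router finds the route that should be quickest rather than shortest,
  so ratios slightly below 1 are possible).
* **actual–optimal time ratio** — observed trip duration divided by the
  free-flow duration of the time-optimal route.
* **driving events** — hard-brake / hard-acceleration counts from
  epoch-to-epoch speed deltas, and overspeeding events/time fraction
  against the nearest edge's posted limit. These proxy the telematics
  vendor's proprietary event detection with an explicit, configurable
  rule (default threshold 15 mph per 30-s epoch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geo import (
    DegenerateTripError,
    GeoPoint,
    haversine_distance,
    haversine_m,
    meters_to_miles,
    path_length_arrays,
)
from .roads import NoRouteError, RoadNetwork, Route, Router, optimal_route, snap_to_network

DEFAULT_EVENT_THRESHOLD_MPH = 15.0  # per 30-s epoch, both brake and accel
DEFAULT_OVERSPEED_TOLERANCE_MPH = 0.0


class UndefinedMetricError(ValueError):
    """Metric undefined for this trip (e.g. zero path length)."""


@dataclass(frozen=True)
class Trip:
    """One trip: strictly increasing timestamps (UTC seconds), fix
    coordinates and speeds (mph), at a nominal epoch spacing."""

    driver_id: str
    trip_id: str
    times: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    speeds_mph: np.ndarray
    epoch_s: float = 30.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        for name in ("times", "lats", "lons", "speeds_mph"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.times.size < 2:
            raise DegenerateTripError("trip needs >= 2 breadcrumbs")
        if not (len(self.times) == len(self.lats) == len(self.lons) == len(self.speeds_mph)):
            raise ValueError("breadcrumb arrays differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.speeds_mph < 0):
            raise ValueError("speeds must be nonnegative")
        if not (np.all(np.isfinite(self.lats)) and np.all(np.isfinite(self.lons))):
            raise ValueError("non-finite coordinates")

    @property
    def n_epochs(self) -> int:
        return int(self.times.size)

    def origin(self) -> GeoPoint:
        return GeoPoint(float(self.lats[0]), float(self.lons[0]))

    def destination(self) -> GeoPoint:
        return GeoPoint(float(self.lats[-1]), float(self.lons[-1]))

    def path_length_m(self) -> float:
        return path_length_arrays(self.lats, self.lons)

    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class TripMetrics:
    """The per-trip metric panel. Ratio fields are ``None`` when no
    network route exists between the snapped endpoints."""

    driver_id: str
    trip_id: str
    distance_mi: float
    straightness: float
    is_loop: bool
    actual_optimal_distance_ratio: float | None
    actual_optimal_time_ratio: float | None
    hard_brake_count: int
    hard_accel_count: int
    overspeed_event_count: int
    overspeed_time_fraction: float


def straightness(trip: Trip) -> tuple[float, bool]:
    """(straightness, is_loop).

    Straightness = haversine(origin, destination) / driven path length,
    in (0, 1] when the endpoints differ. Out-and-back loops return
    (0.0, True). A zero driven path length raises
    :class:`UndefinedMetricError`.
    """
    L = trip.path_length_m()
    if L <= 0.0:
        raise UndefinedMetricError("zero path length")
    direct = haversine_distance(trip.origin(), trip.destination())
    if direct == 0.0:
        return 0.0, True
    return min(direct / L, 1.0), False


def _endpoint_route(trip: Trip, net: RoadNetwork, router: Router | None) -> Route:
    if router is not None:
        o = router.snap(float(trip.lats[0]), float(trip.lons[0]))
        d = router.snap(float(trip.lats[-1]), float(trip.lons[-1]))
        return router.route(o, d)
    o = snap_to_network(net, trip.origin())
    d = snap_to_network(net, trip.destination())
    return optimal_route(net, o, d, criterion="time")


def actual_optimal_distance_ratio(
    trip: Trip, net: RoadNetwork, router: Router | None = None
) -> float:
    """Driven path length over the time-optimal route length between the
    snapped trip endpoints. Raises :class:`NoRouteError` when the
    endpoints are not connected and :class:`UndefinedMetricError` when
    the optimal route has zero length (endpoints snap to one node)."""
    route = _endpoint_route(trip, net, router)
    if route.total_length_m <= 0.0:
        raise UndefinedMetricError("optimal route has zero length")
    return trip.path_length_m() / route.total_length_m


def actual_optimal_time_ratio(
    trip: Trip, net: RoadNetwork, router: Router | None = None
) -> float:
    """Observed trip duration over the optimal route's free-flow duration."""
    route = _endpoint_route(trip, net, router)
    if route.total_duration_s <= 0.0:
        raise UndefinedMetricError("optimal route has zero duration")
    dur = trip.duration_s()
    if dur <= 0.0:
        raise UndefinedMetricError("trip has zero duration")
    return dur / route.total_duration_s


def detect_speed_events(
    trip: Trip,
    brake_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH,
    accel_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH,
) -> tuple[int, int]:
    """Hard-brake and hard-acceleration counts.

    A hard brake is an epoch-to-epoch speed decrease strictly exceeding
    ``brake_threshold_mph``; a hard acceleration, an increase exceeding
    ``accel_threshold_mph``. Each epoch transition contributes at most
    one event of each type.
    """
    d = np.diff(trip.speeds_mph)
    return int(np.sum(d < -brake_threshold_mph)), int(np.sum(d > accel_threshold_mph))


def epoch_speed_limits(trip: Trip, net: RoadNetwork, router: Router | None = None) -> np.ndarray:
    """Posted limit (mph) assigned to each breadcrumb.

    Each fix is snapped to its nearest node; among that node's incident
    edges, the one whose midpoint is nearest the fix supplies the limit.
    Nearest-node (not nearest-edge-projection) assignment is adequate on
    the synthetic grids this package targets.
    """
    if router is None:
        router = Router(net, criterion="time")
    idx = router._idx
    # padded per-node arrays of incident-edge midpoints and limits
    if not hasattr(router, "_incident_cache"):
        per_node: dict[int, list[tuple[float, float, float]]] = {
            i: [] for i in range(len(router.node_ids))
        }
        for e in net.edges:
            pu, pv = net.nodes[e.u], net.nodes[e.v]
            rec = (0.5 * (pu.lat + pv.lat), 0.5 * (pu.lon + pv.lon), e.speed_limit_mph)
            per_node[idx[e.u]].append(rec)
            per_node[idx[e.v]].append(rec)
        width = max(1, max(len(v) for v in per_node.values()))
        n = len(per_node)
        mlat = np.full((n, width), np.nan)
        mlon = np.full((n, width), np.nan)
        mlim = np.full((n, width), np.inf)  # isolated node: nothing to exceed
        for i, recs in per_node.items():
            for j, (a, b, lim) in enumerate(recs):
                mlat[i, j], mlon[i, j], mlim[i, j] = a, b, lim
        router._incident_cache = (mlat, mlon, mlim)
    mlat, mlon, mlim = router._incident_cache
    # nearest node per epoch, vectorized over the node set
    d_nodes = haversine_m(
        trip.lats[:, None], trip.lons[:, None], router.lats[None, :], router.lons[None, :]
    )
    nearest = np.argmin(d_nodes, axis=1)
    d_mid = haversine_m(
        trip.lats[:, None], trip.lons[:, None], mlat[nearest], mlon[nearest]
    )
    d_mid = np.where(np.isnan(d_mid), np.inf, d_mid)
    pick = np.argmin(d_mid, axis=1)
    return mlim[nearest, pick]


def detect_overspeeding(
    trip: Trip,
    net: RoadNetwork,
    tolerance_mph: float = DEFAULT_OVERSPEED_TOLERANCE_MPH,
    router: Router | None = None,
    limits: np.ndarray | None = None,
) -> tuple[int, float]:
    """(event count, fraction of epochs spent overspeeding).

    An epoch is overspeeding when its recorded speed exceeds the local
    posted limit plus ``tolerance_mph``; an event is a maximal run of
    consecutive overspeeding epochs.
    """
    if limits is None:
        limits = epoch_speed_limits(trip, net, router)
    over = trip.speeds_mph > limits + tolerance_mph
    if not over.any():
        return 0, 0.0
    starts = int(over[0]) + int(np.sum(over[1:] & ~over[:-1]))
    return starts, float(np.mean(over))


def compute_trip_metrics(
    trip: Trip,
    net: RoadNetwork,
    router: Router | None = None,
    brake_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH,
    accel_threshold_mph: float = DEFAULT_EVENT_THRESHOLD_MPH,
    overspeed_tolerance_mph: float = DEFAULT_OVERSPEED_TOLERANCE_MPH,
) -> TripMetrics:
    """Full metric panel for one trip. Routing failures leave the two
    actual–optimal ratios as ``None`` (the trip is excluded pairwise from
    driver aggregation) rather than failing the run."""
    s, loop = straightness(trip)
    try:
        dr = actual_optimal_distance_ratio(trip, net, router)
        tr = actual_optimal_time_ratio(trip, net, router)
    except (NoRouteError, UndefinedMetricError) as exc:
        warnings.warn(
            f"trip {trip.trip_id}: routing failed ({exc}); ratios set missing",
            stacklevel=2,
        )
        dr = tr = None
    brakes, accels = detect_speed_events(trip, brake_threshold_mph, accel_threshold_mph)
    ev, frac = detect_overspeeding(trip, net, overspeed_tolerance_mph, router)
    return TripMetrics(
        driver_id=trip.driver_id,
        trip_id=trip.trip_id,
        distance_mi=meters_to_miles(trip.path_length_m()),
        straightness=s,
        is_loop=loop,
        actual_optimal_distance_ratio=dr,
        actual_optimal_time_ratio=tr,
        hard_brake_count=brakes,
        hard_accel_count=accels,
        overspeed_event_count=ev,
        overspeed_time_fraction=frac,
    )
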