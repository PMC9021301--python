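"""Driver-level aggregation of the per-trip metric panel.

Each driver's full trip history is compressed into a single row:
medians of the route metrics, means of the event rates, the radius of
gyration of their recorded positions, and destination-uniqueness
statistics. These are the quantities a cohort table reports one row per
driver.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import haversine_m, meters_to_miles
from .trips import Trip, TripMetrics

DEFAULT_CLUSTER_RADIUS_M = 250.0


@dataclass
class DriverSummary:
    driver_id: str
    enrollment_years: float
    radius_of_gyration_mi: float
    median_distance_mi: float | None
    median_straightness: float | None
    median_actual_optimal_distance_ratio: float | None
    median_actual_optimal_time_ratio: float | None
    trips_per_year: float
    mean_hard_brakes_per_trip: float | None
    mean_hard_accels_per_trip: float | None
    mean_overspeed_events_per_trip: float | None
    mean_overspeed_time_fraction: float | None
    unique_destinations_per_year: float
    unique_destination_ratio: float


def radius_of_gyration(
    lats: np.ndarray, lons: np.ndarray, unit: str = "miles"
) -> float:
    """Root-mean-square great-circle distance of positions from their
    centroid (arithmetic mean of latitude and longitude).

    The standard human-mobility measure of spatial range; by default in
    miles (reporting convention), or meters with ``unit="m"``.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size == 0:
        raise ValueError("radius of gyration needs >= 1 point")
    c_lat, c_lon = float(np.mean(lats)), float(np.mean(lons))
    d = haversine_m(lats, lons, c_lat, c_lon)
    rg_m = float(np.sqrt(np.mean(d**2)))
    if unit == "m":
        return rg_m
    if unit == "miles":
        return meters_to_miles(rg_m)
    raise ValueError(f"unknown unit {unit!r}")


def unique_destinations(
    trips: Sequence[Trip],
    cluster_radius_m: float = DEFAULT_CLUSTER_RADIUS_M,
    enrollment_years: float = 1.0,
) -> tuple[float, float]:
    """(unique destinations per year, unique/total ratio) by greedy
    fixed-radius clustering of trip endpoints.

    Endpoints are processed in trip start-time order; each joins the
    first existing cluster whose *seed* point lies within
    ``cluster_radius_m``, otherwise it seeds a new cluster. Deterministic
    and order-dependent by construction; with radius 0 the count equals
    the number of distinct endpoints regardless of order.
    """
    if not trips:
        raise ValueError("needs >= 1 trip")
    if enrollment_years <= 0:
        raise ValueError("enrollment_years must be positive")
    ordered = sorted(trips, key=lambda t: float(t.times[0]))
    seeds_lat: list[float] = []
    seeds_lon: list[float] = []
    for t in ordered:
        la, lo = float(t.lats[-1]), float(t.lons[-1])
        if seeds_lat:
            d = haversine_m(np.array(seeds_lat), np.array(seeds_lon), la, lo)
            if float(np.min(d)) <= cluster_radius_m:
                continue
        seeds_lat.append(la)
        seeds_lon.append(lo)
    n_unique = len(seeds_lat)
    return n_unique / enrollment_years, n_unique / len(ordered)


def _median(values: Iterable[float | None]) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return None
    return float(np.median(vals))  # even counts: midpoint of central pair


def _mean(values: Iterable[float | None]) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return None
    return float(np.mean(vals))


def summarize_driver(
    metrics: Sequence[TripMetrics],
    trips: Sequence[Trip],
    enrollment_years: float,
    cluster_radius_m: float = DEFAULT_CLUSTER_RADIUS_M,
    gyration_source: str = "breadcrumbs",
) -> DriverSummary:
    """Compress one driver's history into a :class:`DriverSummary`.

    Route metrics are summarized by their median, event rates by their
    mean; per-trip metrics that are missing (failed routing) are excluded
    pairwise. ``gyration_source`` selects whether the radius of gyration
    uses every breadcrumb (default) or trip endpoints only.
    """
    if not metrics or not trips:
        raise ValueError("needs >= 1 trip with metrics")
    if enrollment_years <= 0:
        raise ValueError("enrollment_years must be positive")
    if gyration_source == "breadcrumbs":
        lats = np.concatenate([t.lats for t in trips])
        lons = np.concatenate([t.lons for t in trips])
    elif gyration_source == "endpoints":
        lats = np.array([c for t in trips for c in (t.lats[0], t.lats[-1])])
        lons = np.array([c for t in trips for c in (t.lons[0], t.lons[-1])])
    else:
        raise ValueError(f"unknown gyration_source {gyration_source!r}")
    uniq_per_year, uniq_ratio = unique_destinations(
        trips, cluster_radius_m, enrollment_years
    )
    return DriverSummary(
        driver_id=metrics[0].driver_id,
        enrollment_years=enrollment_years,
        radius_of_gyration_mi=radius_of_gyration(lats, lons),
        median_distance_mi=_median(m.distance_mi for m in metrics),
        median_straightness=_median(m.straightness for m in metrics),
        median_actual_optimal_distance_ratio=_median(
            m.actual_optimal_distance_ratio for m in metrics
        ),
        median_actual_optimal_time_ratio=_median(
            m.actual_optimal_time_ratio for m in metrics
        ),
        trips_per_year=len(metrics) / enrollment_years,
        mean_hard_brakes_per_trip=_mean(m.hard_brake_count for m in metrics),
        mean_hard_accels_per_trip=_mean(m.hard_accel_count for m in metrics),
        mean_overspeed_events_per_trip=_mean(m.overspeed_event_count for m in metrics),
        mean_overspeed_time_fraction=_mean(m.overspeed_time_fraction for m in metrics),
        unique_destinations_per_year=uniq_per_year,
        unique_destination_ratio=uniq_ratio,
    )


#: DriverSummary columns eligible as stability-selection responses.
RESPONSE_COLUMNS = [
    "radius_of_gyration_mi",
    "median_distance_mi",
    "median_straightness",
    "median_actual_optimal_distance_ratio",
    "median_actual_optimal_time_ratio",
    "trips_per_year",
    "mean_hard_brakes_per_trip",
    "mean_hard_accels_per_trip",
    "mean_overspeed_events_per_trip",
    "mean_overspeed_time_fraction",
    "unique_destinations_per_year",
    "unique_destination_ratio",
]


def summaries_to_frame(summaries: Sequence[DriverSummary]) -> pd.DataFrame:
    """One-row-per-driver table, indexed by driver_id."""
    df = pd.DataFrame([asdict(s) for s in summaries])
    return df.set_index("driver_id")
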