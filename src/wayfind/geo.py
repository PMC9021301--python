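"""Great-circle geometry primitives.

All internal lengths are in meters. Miles appear only at reporting
boundaries (driver summary tables are printed in miles); the conversion
constant is :data:`METERS_PER_MILE`.

Distances use the haversine formula on a sphere of radius
:data:`EARTH_RADIUS_M` (IUGG mean Earth radius). Ellipsoidal corrections
are deliberately out of scope: at trip scale (a few km) the spherical
error is far below GPS fix noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: IUGG mean Earth radius, meters.
EARTH_RADIUS_M = 6_371_008.8

#: International mile, meters.
METERS_PER_MILE = 1609.344

#: Statute mph -> m/s.
MPH_TO_MPS = 0.44704


class GeoError(ValueError):
    """Invalid geographic input (non-finite or out-of-range coordinates)."""


class DegenerateTripError(ValueError):
    """A path/trip with fewer than two points."""


@dataclass(frozen=True, slots=True)
class GeoPoint:
    """A WGS84 latitude/longitude pair in decimal degrees.

    Latitude must lie in [-90, 90]; longitude is normalized into
    [-180, 180] on construction.
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise GeoError(f"non-finite coordinates: ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise GeoError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            object.__setattr__(
                self, "lon", ((self.lon + 180.0) % 360.0) - 180.0
            )


def haversine_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, in meters.

    Symmetric, nonnegative, and zero iff the points coincide. The
    haversine formula handles antimeridian-crossing segments without
    special casing.
    """
    return float(
        haversine_m(
            np.asarray(a.lat), np.asarray(a.lon), np.asarray(b.lat), np.asarray(b.lon)
        )
    )


def haversine_m(lat1, lon1, lat2, lon2):
    """Vectorized haversine distance in meters over degree arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # guard rounding excursions above 1 before arcsin
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def path_length(points: Sequence[GeoPoint] | Iterable[GeoPoint]) -> float:
    """Chain length of an ordered point sequence: sum of consecutive
    haversine distances, in meters.

    Raises :class:`DegenerateTripError` for fewer than two points.
    """
    pts = list(points)
    if len(pts) < 2:
        raise DegenerateTripError(f"path needs >= 2 points, got {len(pts)}")
    lats = np.array([p.lat for p in pts])
    lons = np.array([p.lon for p in pts])
    return path_length_arrays(lats, lons)


def path_length_arrays(lats: np.ndarray, lons: np.ndarray) -> float:
    """Chain length over coordinate arrays (meters). Array twin of
    :func:`path_length`."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size < 2:
        raise DegenerateTripError("path needs >= 2 points")
    return float(np.sum(haversine_m(lats[:-1], lons[:-1], lats[1:], lons[1:])))


def meters_to_miles(m: float) -> float:
    return m / METERS_PER_MILE


def miles_to_meters(mi: float) -> float:
    return mi * METERS_PER_MILE
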