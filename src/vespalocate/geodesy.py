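"""Coordinates, compass bearings and circular statistics.

The nest-search method works at the sub-3-km scale of a foraging hornet, so
geographic (lat/lon WGS84) station coordinates are mapped into a local
planar frame in metres before any geometry is done.  The frame is a local
tangent plane centred on a chosen origin (by convention the centroid of the
bait stations), scaled with the WGS84 radii of curvature at the origin:

    x = (lon - lon0) * N(lat0) * cos(lat0)      (metres east)
    y = (lat - lat0) * M(lat0)                  (metres north)

with M and N the meridian and prime-vertical radii of curvature.  Within
the ~50 km working range this agrees with true WGS84 geodesic distances to
well under 0.1% at method scale, and the mapping is exactly invertible.

Bearings follow field compass practice: degrees clockwise from true north,
normalised to [0, 360).  Magnetic-declination correction is the user's
responsibility and is *not* applied here.  Mean vanishing directions are
circular (unit-vector) means -- an arithmetic mean of degree values fails
across the 0/360 wrap (350 and 10 average to 180 instead of 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateDirectionError, OutOfRangeError, ValidationError

# WGS84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_E2 = _WGS84_F * (2.0 - _WGS84_F)

#: Working-range guard: the method operates at a few km; anything beyond
#: this from the frame origin almost certainly means mixed-up coordinates.
MAX_FRAME_RANGE_M = 50_000.0

_RESULTANT_EPS = 1e-9


@dataclass(frozen=True)
class PointGeo:
    """A WGS84 geographic point (decimal degrees)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValidationError("geographic coordinates must be finite")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class PointLocal:
    """A point in a local planar frame: metres east (x) / north (y)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError("local coordinates must be finite")


def normalize_bearing(raw: float) -> float:
    """Normalise a compass bearing to [0, 360) degrees.

    The result is congruent to ``raw`` modulo 360; non-finite input raises
    :class:`~vespalocate.errors.ValidationError`.
    """
    raw = float(raw)
    if not math.isfinite(raw):
        raise ValidationError(f"bearing must be finite, got {raw!r}")
    value = raw % 360.0
    # float modulo can round a tiny negative up to exactly 360.0
    return 0.0 if value == 360.0 else value


def bearing_between(origin: PointLocal, target: PointLocal) -> float:
    """Compass bearing (deg clockwise from north) from *origin* to *target*."""
    dx, dy = target.x - origin.x, target.y - origin.y
    if dx == 0.0 and dy == 0.0:
        raise ValidationError("bearing undefined for coincident points")
    return normalize_bearing(math.degrees(math.atan2(dx, dy)))


def bearing_unit_vector(bearing_deg: float) -> tuple[float, float]:
    """Planar unit vector (east, north) pointing along a compass bearing."""
    rad = math.radians(bearing_deg)
    return math.sin(rad), math.cos(rad)


def circular_mean(bearings: Sequence[float]) -> float:
    """Circular (unit-vector) mean of compass bearings, in [0, 360).

    Raises :class:`DegenerateDirectionError` when the resultant vector is
    (numerically) zero, e.g. for antipodal bearings [0, 180] -- in the field
    this signals internally inconsistent observations for one individual.
    """
    b = np.asarray([normalize_bearing(v) for v in bearings], dtype=float)
    if b.size == 0:
        raise ValidationError("circular_mean of an empty bearing list")
    rad = np.deg2rad(b)
    c, s = float(np.cos(rad).mean()), float(np.sin(rad).mean())
    if math.hypot(c, s) < _RESULTANT_EPS:
        raise DegenerateDirectionError(
            "bearings cancel out (resultant length < 1e-9); "
            "observations are inconsistent"
        )
    return normalize_bearing(math.degrees(math.atan2(s, c)))


def circular_dispersion(bearings: Sequence[float]) -> float:
    """Circular standard deviation of bearings, in degrees.

    Uses the resultant length R: csd = sqrt(-2 ln R) (radians), converted to
    degrees.  Zero iff all bearings coincide.  Needs at least two bearings;
    antipodal/cancelled bearing sets raise :class:`DegenerateDirectionError`.
    """
    b = np.asarray([normalize_bearing(v) for v in bearings], dtype=float)
    if b.size < 2:
        raise ValidationError("circular_dispersion needs at least 2 bearings")
    rad = np.deg2rad(b)
    r = float(np.hypot(np.cos(rad).mean(), np.sin(rad).mean()))
    if r < _RESULTANT_EPS:
        raise DegenerateDirectionError(
            "bearings cancel out; dispersion is unbounded"
        )
    r = min(r, 1.0)  # guard against rounding slightly above 1
    return math.degrees(math.sqrt(max(-2.0 * math.log(r), 0.0)))


class LocalFrame:
    """Local tangent-plane frame centred on a geographic origin.

    Maps WGS84 lat/lon to metric east/north offsets and back.  Instances
    compare equal when their origins coincide, so geometry built in two
    frames with the same origin can be intersected.
    """

    def __init__(self, origin: PointGeo):
        self.origin = origin
        lat0 = math.radians(origin.lat)
        s2 = _WGS84_E2 * math.sin(lat0) ** 2
        # meridian (M) and prime-vertical (N) radii of curvature at origin
        self._m = _WGS84_A * (1.0 - _WGS84_E2) / (1.0 - s2) ** 1.5
        self._n_coslat = _WGS84_A / math.sqrt(1.0 - s2) * math.cos(lat0)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LocalFrame) and self.origin == other.origin

    def __hash__(self) -> int:
        return hash(self.origin)

    def __repr__(self) -> str:
        return f"LocalFrame(origin={self.origin!r})"

    def to_local(self, point: PointGeo) -> PointLocal:
        x = math.radians(point.lon - self.origin.lon) * self._n_coslat
        y = math.radians(point.lat - self.origin.lat) * self._m
        if math.hypot(x, y) > MAX_FRAME_RANGE_M:
            raise OutOfRangeError(
                f"point {point} is {math.hypot(x, y) / 1000:.1f} km from the "
                f"frame origin (> {MAX_FRAME_RANGE_M / 1000:.0f} km); "
                "check for swapped or mixed-up coordinates"
            )
        return PointLocal(x, y)

    def to_geographic(self, point: PointLocal) -> PointGeo:
        lon = self.origin.lon + math.degrees(point.x / self._n_coslat)
        lat = self.origin.lat + math.degrees(point.y / self._m)
        return PointGeo(lat, lon)


def to_local_frame(
    points: Iterable[PointGeo], origin: PointGeo
) -> tuple[list[PointLocal], LocalFrame]:
    """Project geographic points into a local frame centred on *origin*."""
    frame = LocalFrame(origin)
    return [frame.to_local(p) for p in points], frame


def frame_from_stations(points: Sequence[PointGeo]) -> LocalFrame:
    """Frame centred on the centroid of the given geographic points."""
    if not points:
        raise ValidationError("cannot build a frame from zero points")
    lat = sum(p.lat for p in points) / len(points)
    lon = sum(p.lon for p in points) / len(points)
    return LocalFrame(PointGeo(lat, lon))


#: Sentinel frame used when inputs are already planar (x/y metres); all
#: planar datasets share it, so frame-identity checks still work.
PLANAR_FRAME = object()
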