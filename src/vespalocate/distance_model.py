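"""Distance-band estimation from round-trip times.

A marked hornet's bait-nest-bait round trip of duration t_t comprises two
flight legs plus a fixed nest-handling time t_n spent delivering food.
Assuming straight symmetric legs, the one-way distance is

    D = ((t_t - t_n) / 2) * S

for a flight speed S.  Since the true speed is unknown, bracketing speeds
S_min and S_max turn the *shortest* observed round trip of an individual
into a distance band [D_min, D_max].  Defaults: t_n = 45 s, S_min = 1.8 m/s
(field-measured loaded flight), S_max = 5.4 m/s (literature maximum for
homing hornets, deliberately conservative: it enlarges the search area).

The bearing sector around the mean vanishing direction uses a half-angle of
10 deg for short trips and 15 deg for long ones (threshold 10 min): the
farther the nest, the more the homing route can deviate from the vanishing
direction seen at the bait, so the likely area must be widened.

Estimation is strictly per individual: in high-density areas a single bait
attracts hornets from multiple nests, so pooling times across individuals
would mix distances to different nests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InfeasibleTripError, ValidationError
from .geodesy import circular_dispersion, circular_mean, normalize_bearing


@dataclass(frozen=True)
class ModelConstants:
    """Tunable constants of the distance/sector model (defaults = field values).

    t_nest_s: time spent on the nest per visit, seconds.
    s_min / s_max: bracketing flight speeds, m/s.
    angle_short / angle_long: sector half-angles, degrees.
    trip_time_threshold_s: round-trip time separating the two angle regimes.
    min_trips: minimum number of observed round trips per individual.
    """

    t_nest_s: float = 45.0
    s_min: float = 1.8
    s_max: float = 5.4
    angle_short_deg: float = 10.0
    angle_long_deg: float = 15.0
    trip_time_threshold_s: float = 600.0
    min_trips: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.s_min < self.s_max:
            raise ValidationError("need 0 < s_min < s_max")
        if self.t_nest_s < 0.0:
            raise ValidationError("t_nest_s must be >= 0")
        if not 0.0 < self.angle_short_deg <= self.angle_long_deg < 90.0:
            raise ValidationError("need 0 < angle_short <= angle_long < 90")
        if self.trip_time_threshold_s <= self.t_nest_s:
            raise ValidationError("trip_time_threshold_s must exceed t_nest_s")
        if self.min_trips < 1:
            raise ValidationError("min_trips must be >= 1")


@dataclass(frozen=True)
class TripObservation:
    """One observed bait-nest-bait round trip of one marked individual."""

    station_id: str
    hornet_id: str
    bearing_deg: float
    round_trip_s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.round_trip_s) and self.round_trip_s > 0):
            raise ValidationError(
                f"round_trip_s must be finite and > 0, got {self.round_trip_s}"
            )
        object.__setattr__(
            self, "bearing_deg", normalize_bearing(self.bearing_deg)
        )


@dataclass(frozen=True)
class IndividualTrack:
    """Per-individual aggregate at one station.

    t_min_s is the shortest observed round trip -- the best available proxy
    for an unhindered direct trip; longer trips include detours or waiting.
    """

    station_id: str
    hornet_id: str
    n_trips: int
    t_min_s: float
    mean_bearing_deg: float
    bearing_dispersion_deg: float | None


@dataclass(frozen=True)
class DistanceBand:
    """Bracketing one-way distance estimate [d_min, d_max] in metres."""

    d_min_m: float
    d_max_m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_min_m < self.d_max_m:
            raise ValidationError("need 0 <= d_min < d_max")


@dataclass(frozen=True)
class UsabilityReport:
    """Outcome of the usability screen for one track."""

    usable: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def aggregate_tracks(
    observations: list[TripObservation],
) -> list[IndividualTrack]:
    """Group observations into one track per (station, individual).

    Computes trip count, minimum round-trip time, circular mean bearing and
    circular dispersion (None for a single trip).  Output is ordered by
    station id then hornet id, so downstream results are deterministic.
    """
    if not observations:
        raise ValidationError("no trip observations supplied")
    groups: dict[tuple[str, str], list[TripObservation]] = {}
    for obs in observations:
        groups.setdefault((obs.station_id, obs.hornet_id), []).append(obs)
    tracks = []
    for (station_id, hornet_id), obs_list in sorted(groups.items()):
        bearings = [o.bearing_deg for o in obs_list]
        tracks.append(
            IndividualTrack(
                station_id=station_id,
                hornet_id=hornet_id,
                n_trips=len(obs_list),
                t_min_s=min(o.round_trip_s for o in obs_list),
                mean_bearing_deg=circular_mean(bearings),
                bearing_dispersion_deg=(
                    circular_dispersion(bearings) if len(bearings) >= 2 else None
                ),
            )
        )
    return tracks


def estimate_distance_band(
    t_min_s: float, constants: ModelConstants = ModelConstants()
) -> DistanceBand:
    """Distance band from the shortest round trip: D = ((t - t_n)/2) * S.

    Raises :class:`InfeasibleTripError` when the trip is not longer than the
    nest-handling time -- a zero/negative flight time indicates a mistimed
    observation or confused individual identity, not a nest at the bait.
    """
    flight_s = t_min_s - constants.t_nest_s
    if flight_s <= 0.0:
        raise InfeasibleTripError(
            f"round trip of {t_min_s:.0f} s is not longer than the "
            f"nest-handling time ({constants.t_nest_s:.0f} s)"
        )
    half = flight_s / 2.0
    return DistanceBand(half * constants.s_min, half * constants.s_max)


def select_half_angle(
    t_min_s: float, constants: ModelConstants = ModelConstants()
) -> float:
    """Sector half-angle for an individual's minimum round-trip time.

    Strictly below the threshold (default 10 min) the narrow angle applies;
    at or above it, the wide one.  The tie at exactly the threshold takes
    the wide angle: enlarging the search area can only add ground to check,
    never lose the nest.
    """
    if t_min_s <= 0:
        raise ValidationError("t_min_s must be > 0")
    if t_min_s < constants.trip_time_threshold_s:
        return constants.angle_short_deg
    return constants.angle_long_deg


def check_track_usable(
    track: IndividualTrack, constants: ModelConstants = ModelConstants()
) -> UsabilityReport:
    """Screen a track against the minimum-trips and feasible-time rules."""
    reasons = []
    if track.n_trips < constants.min_trips:
        reasons.append(
            f"insufficient trips ({track.n_trips} < {constants.min_trips})"
        )
    if track.t_min_s <= constants.t_nest_s:
        reasons.append(
            f"trip shorter than nest-handling time "
            f"({track.t_min_s:.0f} s <= {constants.t_nest_s:.0f} s)"
        )
    return UsabilityReport(usable=not reasons, reasons=tuple(reasons))
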