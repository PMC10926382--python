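"""Likely-area geometry: bearing sectors, distance annuli, convergence.

For one usable individual at one station the likely nest area is the
intersection of

* the annulus d_min <= |p - station| <= d_max given by the distance band, and
* the wedge of bearings within the half-angle of the mean vanishing
  direction (the two "external lines" drawn on the field map).

Regions from different stations that point at the same nest are intersected
into the *convergent area*, which is never larger than any input region and
is where the visual search starts.  Individuals at one bait can come from
different nests, so blanket intersection of everything is deliberately not
the only output: pairwise intersections are reported alongside the full one.

All geometry lives in a local planar frame (metres); arcs are discretised
at a configurable step (default 1 deg per vertex, area error < 0.01%,
negligible against the 3x speed bracket).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import reduce
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry

from .distance_model import (
    DistanceBand,
    IndividualTrack,
    ModelConstants,
    check_track_usable,
    estimate_distance_band,
    select_half_angle,
)
from .errors import FrameMismatchError, ValidationError
from .geodesy import PointLocal, bearing_unit_vector

DEFAULT_ARC_STEP_DEG = 1.0


@dataclass(frozen=True)
class LikelyRegion:
    """A polygonal likely-nest area with provenance.

    kind is "single-track" for one sector-annulus, "convergent" for an
    intersection of several.  ``frame`` identifies the local frame the
    coordinates live in; regions from different frames cannot be combined.
    """

    polygon: BaseGeometry
    provenance: tuple[tuple[str, str], ...]  # (station_id, hornet_id)
    kind: str
    frame: object = None
    band: DistanceBand | None = None
    mean_bearing_deg: float | None = None
    half_angle_deg: float | None = None
    apex: PointLocal | None = None
    diagnostic: str | None = None
    #: boundary tolerance inherited from arc discretisation, metres
    boundary_tol_m: float = 0.0

    @property
    def area_m2(self) -> float:
        return float(self.polygon.area)

    @property
    def is_empty(self) -> bool:
        return self.polygon.is_empty


def _arc_points(
    apex: PointLocal,
    radius: float,
    start_deg: float,
    end_deg: float,
    arc_step: float,
) -> np.ndarray:
    """Vertices along a compass-bearing arc, start to end (degrees)."""
    n_seg = max(1, math.ceil(abs(end_deg - start_deg) / arc_step))
    ang = np.deg2rad(np.linspace(start_deg, end_deg, n_seg + 1))
    return np.column_stack(
        (apex.x + radius * np.sin(ang), apex.y + radius * np.cos(ang))
    )


def build_sector_annulus(
    station: PointLocal,
    track: IndividualTrack,
    constants: ModelConstants = ModelConstants(),
    arc_step: float = DEFAULT_ARC_STEP_DEG,
    frame: object = None,
) -> LikelyRegion:
    """Likely area for one usable track: bearing sector ∩ distance annulus.

    The polygon runs counter-clockwise: outer arc at d_max from the +half
    to the -half external line (compass angles increase clockwise, so this
    traverses counter-clockwise in the x/y plane), then the inner arc at
    d_min back.  Area matches the closed form (2a/360)*pi*(d_max^2-d_min^2)
    to well under 0.5% at the default arc step.
    """
    if not 0.0 < arc_step <= 5.0:
        raise ValidationError("arc_step must be in (0, 5] degrees")
    report = check_track_usable(track, constants)
    if not report.usable:
        raise ValidationError(
            f"track ({track.station_id}, {track.hornet_id}) not usable: "
            + "; ".join(report.reasons)
        )
    band = estimate_distance_band(track.t_min_s, constants)
    half_angle = select_half_angle(track.t_min_s, constants)
    b0 = track.mean_bearing_deg
    outer = _arc_points(
        station, band.d_max_m, b0 + half_angle, b0 - half_angle, arc_step
    )
    inner = _arc_points(
        station, band.d_min_m, b0 - half_angle, b0 + half_angle, arc_step
    )
    polygon = Polygon(np.vstack((outer, inner)))
    # chord sagitta bounds how far the polygon boundary sits off the true arcs
    # 5% headroom so points exactly on the true arc never fail by rounding
    sagitta = 1.05 * band.d_max_m * (1.0 - math.cos(math.radians(arc_step) / 2.0))
    return LikelyRegion(
        polygon=polygon,
        provenance=((track.station_id, track.hornet_id),),
        kind="single-track",
        frame=frame,
        band=band,
        mean_bearing_deg=b0,
        half_angle_deg=half_angle,
        apex=station,
        boundary_tol_m=max(sagitta, 1e-9),
    )


def intersect_regions(regions: Sequence[LikelyRegion]) -> LikelyRegion:
    """Convergent area: intersection of two or more likely regions.

    An empty intersection is a legitimate field outcome (bearings that do
    not converge), returned as an explicit empty region with a diagnostic
    rather than raised -- the suggested remedy is to re-run with the wide
    half-angle on all tracks.
    """
    if len(regions) < 2:
        raise ValidationError("need at least 2 regions to intersect")
    frames = {r.frame for r in regions}
    if len(frames) > 1:
        raise FrameMismatchError(
            "regions come from different local frames; reproject first"
        )
    geom = reduce(lambda a, b: a.intersection(b), (r.polygon for r in regions))
    provenance = tuple(
        dict.fromkeys(p for r in regions for p in r.provenance)
    )
    lead = regions[0]
    return LikelyRegion(
        polygon=geom,
        provenance=provenance,
        kind="convergent",
        frame=lead.frame,
        apex=lead.apex,
        mean_bearing_deg=lead.mean_bearing_deg,
        boundary_tol_m=max(r.boundary_tol_m for r in regions),
        diagnostic=(
            "no convergence: likely areas do not overlap; consider "
            "re-running with the wide half-angle on all tracks"
            if geom.is_empty
            else None
        ),
    )


def containment_check(region: LikelyRegion, point: PointLocal) -> bool:
    """True iff *point* lies inside the region or on its boundary.

    Boundary membership is judged to the region's discretisation tolerance,
    so points on the true (un-discretised) arcs still count as contained.
    """
    p = Point(point.x, point.y)
    if region.polygon.is_empty:
        return False
    return bool(
        region.polygon.covers(p)
        or region.polygon.distance(p) <= region.boundary_tol_m
    )


def suggest_second_station(
    region: LikelyRegion, margin: float
) -> PointLocal:
    """Placement for a second bait station: near but outside the likely area.

    Hornets tend not to visit protein baits in the immediate vicinity of
    the nest, so the station goes *outside* the region, just beyond its far
    boundary along the mean bearing axis from the originating station.  The
    returned point sits at 1.5x *margin* from the region boundary
    (within the contracted [margin, 2*margin] ring) and is deterministic.
    """
    if margin <= 0:
        raise ValidationError("margin must be > 0")
    if region.is_empty:
        raise ValidationError("cannot place a station for an empty region")
    if region.apex is None or region.mean_bearing_deg is None:
        raise ValidationError("region lacks an originating station/bearing")
    ux, uy = bearing_unit_vector(region.mean_bearing_deg)
    coords = np.asarray(
        region.polygon.exterior.coords
        if isinstance(region.polygon, Polygon)
        else [pt for g in region.polygon.geoms for pt in g.exterior.coords]
    )
    proj = (coords[:, 0] - region.apex.x) * ux + (coords[:, 1] - region.apex.y) * uy
    far = coords[int(np.argmax(proj))]
    return PointLocal(
        float(far[0] + 1.5 * margin * ux), float(far[1] + 1.5 * margin * uy)
    )


@dataclass(frozen=True)
class LocalizationResult:
    """Output of the full per-station-set localization step."""

    single_regions: tuple[LikelyRegion, ...]
    pairwise_convergent: tuple[LikelyRegion, ...] = field(default_factory=tuple)
    full_convergent: LikelyRegion | None = None


def localize(
    stations: dict[str, PointLocal],
    tracks: Sequence[IndividualTrack],
    constants: ModelConstants = ModelConstants(),
    arc_step: float = DEFAULT_ARC_STEP_DEG,
    frame: object = None,
) -> LocalizationResult:
    """Build all single-track regions and their cross-station convergences.

    Only usable tracks contribute (callers screen and log exclusions).
    Pairwise convergent areas are built for every pair of regions from
    *different* stations; when two or more regions exist, the intersection
    of all of them is also reported.  With several nests feeding one bait
    the full intersection can be empty while a pairwise one is not.
    """
    regions = []
    for track in tracks:
        if track.station_id not in stations:
            raise ValidationError(f"unknown station id {track.station_id!r}")
        regions.append(
            build_sector_annulus(
                stations[track.station_id], track, constants, arc_step, frame
            )
        )
    pairwise = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if regions[i].provenance[0][0] != regions[j].provenance[0][0]:
                pairwise.append(intersect_regions([regions[i], regions[j]]))
    full = intersect_regions(regions) if len(regions) >= 2 else None
    return LocalizationResult(
        single_regions=tuple(regions),
        pairwise_convergent=tuple(pairwise),
        full_convergent=full,
    )
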