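"""CSV readers, GeoJSON writer and config parsing.

Input tables are plain UTF-8 comma-separated files with a header row and
"." as decimal separator:

stations.csv
    station_id, lat, lon          (crs_mode = geographic)
    station_id, x_m, y_m          (crs_mode = planar)

trips.csv
    station_id, hornet_id, bearing_deg, round_trip_s
    -- or, instead of round_trip_s --
    station_id, hornet_id, bearing_deg, depart_time, return_time
    with ISO-8601 timestamps; durations are return - depart in seconds.
    Timestamps without timezone are treated as local wall-clock and only
    ever differenced, never absolutised.

Likely regions are exported as an RFC 7946 GeoJSON FeatureCollection.  In
geographic mode polygon coordinates are WGS84 lon/lat (the planar metric
ring is echoed in each feature's properties); in planar mode coordinates
are raw x/y metres and the collection carries a frame descriptor.
"""

from __future__ import annotations

import configparser
import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd
from shapely.geometry import Polygon

from .distance_model import ModelConstants, TripObservation
from .errors import SchemaError, ValidationError
from .geodesy import PLANAR_FRAME, LocalFrame, PointGeo, PointLocal, normalize_bearing
from .localization import LikelyRegion
from .simulator import BaitStation, SimulationScenario, TruncatedNormal


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_stations(path, crs_mode: str = "geographic") -> list[BaitStation]:
    """Read the bait-station table; duplicate ids are rejected."""
    if crs_mode not in ("geographic", "planar"):
        raise ValidationError(f"unknown crs_mode {crs_mode!r}")
    df = pd.read_csv(path)
    _require_columns(df, ["station_id"], path)
    dupes = df["station_id"].astype(str)[df["station_id"].astype(str).duplicated()]
    if not dupes.empty:
        raise ValidationError(
            f"{path}: duplicate station id(s): {', '.join(sorted(set(dupes)))}"
        )
    stations = []
    if crs_mode == "geographic":
        _require_columns(df, ["lat", "lon"], path)
        for row in df.itertuples(index=False):
            stations.append(
                BaitStation(str(row.station_id), PointGeo(float(row.lat), float(row.lon)))
            )
    else:
        _require_columns(df, ["x_m", "y_m"], path)
        for row in df.itertuples(index=False):
            stations.append(
                BaitStation(str(row.station_id), PointLocal(float(row.x_m), float(row.y_m)))
            )
    return stations


def read_trips(path) -> list[TripObservation]:
    """Read the trip-observation table.

    Accepts exactly one duration encoding: a ``round_trip_s`` column, or a
    ``depart_time``/``return_time`` ISO-8601 pair.  Bearings are normalised
    to [0, 360).  Rows with non-positive or unparseable durations raise a
    row-numbered error (header = line 1, first data row = line 2).
    """
    df = pd.read_csv(path)
    _require_columns(df, ["station_id", "hornet_id", "bearing_deg"], path)
    has_rt = "round_trip_s" in df.columns
    has_ts = "depart_time" in df.columns and "return_time" in df.columns
    if has_rt == has_ts:
        raise SchemaError(
            f"{path}: provide either a round_trip_s column or a "
            "depart_time/return_time pair, not both or neither"
        )
    if has_ts:
        try:
            depart = pd.to_datetime(df["depart_time"], format="ISO8601")
            ret = pd.to_datetime(df["return_time"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: unparseable timestamp: {exc}") from exc
        durations = (ret - depart).dt.total_seconds()
    else:
        durations = pd.to_numeric(df["round_trip_s"], errors="coerce")
    bad = df.index[~(durations > 0) | durations.isna()] + 2
    if len(bad):
        raise ValidationError(
            f"{path}: non-positive or invalid round-trip duration on "
            f"line(s) {', '.join(map(str, bad))}"
        )
    return [
        TripObservation(
            station_id=str(row.station_id),
            hornet_id=str(row.hornet_id),
            bearing_deg=normalize_bearing(float(row.bearing_deg)),
            round_trip_s=float(dur),
        )
        for row, dur in zip(df.itertuples(index=False), durations)
    ]


def write_stations_csv(stations: Sequence[BaitStation], path) -> None:
    rows = []
    for s in stations:
        if isinstance(s.position, PointLocal):
            rows.append({"station_id": s.station_id, "x_m": s.position.x, "y_m": s.position.y})
        else:
            rows.append({"station_id": s.station_id, "lat": s.position.lat, "lon": s.position.lon})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trips_csv(trips: Sequence[TripObservation], path) -> None:
    pd.DataFrame(
        {
            "station_id": [t.station_id for t in trips],
            "hornet_id": [t.hornet_id for t in trips],
            "bearing_deg": [round(t.bearing_deg, 6) for t in trips],
            "round_trip_s": [round(t.round_trip_s, 3) for t in trips],
        }
    ).to_csv(path, index=False)


def _ring_coords(polygon: Polygon) -> list[list[list[float]]]:
    rings = [list(polygon.exterior.coords)]
    rings.extend(list(r.coords) for r in polygon.interiors)
    return [[[round(x, 6), round(y, 6)] for x, y in ring] for ring in rings]


def _region_polygons(region: LikelyRegion) -> list[Polygon]:
    geom = region.polygon
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    return [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]


def region_to_feature(region: LikelyRegion, frame) -> dict:
    """One likely region as a GeoJSON Feature (empty regions → null geometry)."""
    polys = _region_polygons(region)
    local_rings = [_ring_coords(p) for p in polys]
    if frame is PLANAR_FRAME or frame is None:
        out_rings = local_rings
    else:
        out_rings = [
            [
                [
                    [round(g.lon, 8), round(g.lat, 8)]
                    for g in (frame.to_geographic(PointLocal(x, y)) for x, y in ring)
                ]
                for ring in rings
            ]
            for rings in local_rings
        ]
    if not out_rings:
        geometry = None
    elif len(out_rings) == 1:
        geometry = {"type": "Polygon", "coordinates": out_rings[0]}
    else:
        geometry = {"type": "MultiPolygon", "coordinates": out_rings}
    properties = {
        "kind": region.kind,
        "station_ids": sorted({p[0] for p in region.provenance}),
        "hornet_ids": sorted({p[1] for p in region.provenance}),
        "d_min_m": region.band.d_min_m if region.band else None,
        "d_max_m": region.band.d_max_m if region.band else None,
        "mean_bearing_deg": region.mean_bearing_deg,
        "half_angle_deg": region.half_angle_deg,
        "area_m2": round(region.area_m2, 3),
        "diagnostic": region.diagnostic,
    }
    if frame is not PLANAR_FRAME and frame is not None:
        properties["coordinates_local_m"] = local_rings
    return {"type": "Feature", "geometry": geometry, "properties": properties}


def write_regions_geojson(regions: Sequence[LikelyRegion], frame, path) -> None:
    """Write likely regions as a GeoJSON FeatureCollection.

    An empty region *list* is an error (nothing to write); individual empty
    convergent regions are kept as null-geometry features so their
    diagnostics survive into the output.
    """
    if not regions:
        raise ValidationError("no regions to write")
    collection = {
        "type": "FeatureCollection",
        "features": [region_to_feature(r, frame) for r in regions],
    }
    if frame is PLANAR_FRAME or frame is None:
        collection["metadata"] = {
            "crs_mode": "planar",
            "frame": "local metric frame; coordinates are metres east/north of the dataset origin",
        }
    else:
        collection["metadata"] = {
            "crs_mode": "geographic",
            "frame_origin": {"lat": frame.origin.lat, "lon": frame.origin.lon},
        }
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(collection, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise ValidationError(f"cannot write GeoJSON to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# configuration

_MODEL_KEYS = {
    "t_nest": "t_nest_s",
    "s_min": "s_min",
    "s_max": "s_max",
    "angle_short": "angle_short_deg",
    "angle_long": "angle_long_deg",
    "threshold_s": "trip_time_threshold_s",
    "min_trips": "min_trips",
}


def load_config(path) -> configparser.ConfigParser:
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ValidationError(f"config file not found: {path}")
    return parser


def constants_from_config(parser: configparser.ConfigParser) -> ModelConstants:
    """Model constants from the [model] section; absent keys keep defaults."""
    kwargs = {}
    if parser.has_section("model"):
        for key, field_name in _MODEL_KEYS.items():
            if parser.has_option("model", key):
                raw = parser.get("model", key)
                kwargs[field_name] = int(raw) if field_name == "min_trips" else float(raw)
    return ModelConstants(**kwargs)


def scenario_from_config(parser: configparser.ConfigParser, seed: int | None = None) -> SimulationScenario:
    """Build a simulation scenario from the [simulation] section.

    Stations are given as ``stations = ID:x:y, ID:x:y, ...`` in metres of
    the local frame; the true nest as ``nest_x_m`` / ``nest_y_m``.
    """
    if not parser.has_section("simulation"):
        raise SchemaError("config has no [simulation] section")
    sim = parser["simulation"]
    try:
        stations = tuple(
            BaitStation(sid.strip(), PointLocal(float(x), float(y)))
            for sid, x, y in (
                entry.strip().split(":")
                for entry in sim["stations"].split(",")
                if entry.strip()
            )
        )
        scenario = SimulationScenario(
            true_nest=PointLocal(float(sim["nest_x_m"]), float(sim["nest_y_m"])),
            stations=stations,
            n_hornets_per_station=sim.getint("n_hornets_per_station", 2),
            trips_per_hornet=sim.getint("trips_per_hornet", 4),
            speed_model=TruncatedNormal(
                mean=sim.getfloat("speed_mean", 2.7),
                sd=sim.getfloat("speed_sd", 0.5),
                lower=sim.getfloat("speed_lower", 1.8),
                upper=sim.getfloat("speed_upper", 5.4),
            ),
            handling_model=TruncatedNormal(
                mean=sim.getfloat("handling_mean", 45.0),
                sd=sim.getfloat("handling_sd", 10.0),
                lower=sim.getfloat("handling_lower", 5.0),
                upper=sim.getfloat("handling_upper", math.inf),
            ),
            bearing_noise_sd=sim.getfloat("bearing_noise_sd", 3.0),
            seed=seed if seed is not None else sim.getint("seed", 0),
        )
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"invalid [simulation] section: {exc}") from exc
    return scenario


def write_truth_json(scenario: SimulationScenario, path) -> None:
    payload = {
        "true_nest": {"x_m": scenario.true_nest.x, "y_m": scenario.true_nest.y},
        "seed": scenario.seed,
        "n_hornets_per_station": scenario.n_hornets_per_station,
        "trips_per_hornet": scenario.trips_per_hornet,
        "speed_model": {
            k: (v if math.isfinite(v) else None)
            for k, v in vars(scenario.speed_model).items()
        },
        "handling_model": {
            k: (v if math.isfinite(v) else None)
            for k, v in vars(scenario.handling_model).items()
        },
        "bearing_noise_sd_deg": scenario.bearing_noise_sd,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
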