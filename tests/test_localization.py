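"""Sector-annulus geometry, convergence, containment, station placement."""

import math

import numpy as np
import pytest
from shapely.geometry import Point

from vespalocate.distance_model import IndividualTrack, ModelConstants, estimate_distance_band
from vespalocate.errors import FrameMismatchError, ValidationError
from vespalocate.geodesy import PointLocal
from vespalocate.localization import (
    build_sector_annulus,
    containment_check,
    intersect_regions,
    localize,
    suggest_second_station,
)

ORIGIN = PointLocal(0.0, 0.0)


def _track(t_min, bearing=0.0, station="BS1", hornet="YB", n=3):
    return IndividualTrack(station, hornet, n, t_min, bearing, None)


def closed_form_area(t_min, constants=ModelConstants()):
    """Independent oracle: (2a/360) * pi * (d_max^2 - d_min^2)."""
    band = estimate_distance_band(t_min, constants)
    half = 10.0 if t_min < constants.trip_time_threshold_s else 15.0
    return (2 * half / 360.0) * math.pi * (band.d_max_m**2 - band.d_min_m**2)


class TestSectorAnnulus:
    def test_reference_area(self):
        # t_min 345 s: band [270, 810] m, half-angle 10 deg -> 32400*pi m^2
        region = build_sector_annulus(ORIGIN, _track(345.0))
        assert region.area_m2 == pytest.approx(32400 * math.pi, rel=5e-3)
        assert region.half_angle_deg == 10.0

    @pytest.mark.parametrize("t_min", [150, 240, 345, 420, 540, 600, 720, 900, 1200, 1800])
    @pytest.mark.parametrize("bearing", [0.0, 237.0])
    def test_area_matches_closed_form(self, t_min, bearing):
        region = build_sector_annulus(ORIGIN, _track(float(t_min), bearing))
        assert region.area_m2 == pytest.approx(closed_form_area(t_min), rel=5e-3)

    def test_area_error_shrinks_with_arc_step(self):
        track = _track(345.0)
        oracle = closed_form_area(345.0)
        errs = [
            abs(build_sector_annulus(ORIGIN, track, arc_step=s).area_m2 - oracle)
            for s in (5.0, 1.0, 0.2)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_monte_carlo_area_oracle(self):
        """Uniform point classification reproduces the area within 3 SE."""
        region = build_sector_annulus(ORIGIN, _track(345.0, bearing=30.0))
        minx, miny, maxx, maxy = region.polygon.bounds
        box_area = (maxx - minx) * (maxy - miny)
        rng = np.random.default_rng(12345)
        n = 100_000
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        inside = sum(
            containment_check(region, PointLocal(x, y)) for x, y in zip(xs, ys)
        )
        p_hat = inside / n
        estimate = p_hat * box_area
        se = box_area * math.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(estimate - region.area_m2) <= 3 * se

    def test_vertices_satisfy_band_and_sector(self):
        track = _track(345.0, bearing=75.0)
        region = build_sector_annulus(ORIGIN, track)
        tol = region.boundary_tol_m
        band = region.band
        for x, y in region.polygon.exterior.coords:
            d = math.hypot(x, y)
            assert band.d_min_m - tol <= d <= band.d_max_m + tol
            dev = (math.degrees(math.atan2(x, y)) - 75.0 + 180) % 360 - 180
            assert abs(dev) <= region.half_angle_deg + 1e-6

    def test_polygon_is_ccw_and_simple(self):
        region = build_sector_annulus(ORIGIN, _track(345.0, bearing=300.0))
        assert region.polygon.exterior.is_ccw
        assert region.polygon.is_valid

    def test_wide_angle_enlarges_area(self):
        # same distance band, half-angle 15 vs 10 -> strictly larger area
        short = build_sector_annulus(ORIGIN, _track(599.0))
        long = build_sector_annulus(ORIGIN, _track(601.0))
        band_ratio = (
            closed_form_area(601.0) / closed_form_area(599.0)
        )
        assert long.area_m2 / short.area_m2 == pytest.approx(band_ratio, rel=1e-3)
        assert long.half_angle_deg > short.half_angle_deg

    def test_unusable_track_rejected(self):
        with pytest.raises(ValidationError):
            build_sector_annulus(ORIGIN, _track(345.0, n=2))

    def test_bad_arc_step_rejected(self):
        with pytest.raises(ValidationError):
            build_sector_annulus(ORIGIN, _track(345.0), arc_step=10.0)


class TestIntersect:
    def _two_overlapping(self):
        r1 = build_sector_annulus(ORIGIN, _track(345.0, bearing=0.0))
        r2 = build_sector_annulus(
            PointLocal(400.0, 540.0), _track(345.0, bearing=270.0, station="BS2")
        )
        return r1, r2

    def test_self_intersection_idempotent(self):
        r1, _ = self._two_overlapping()
        conv = intersect_regions([r1, r1])
        assert conv.area_m2 == pytest.approx(r1.area_m2, rel=1e-6)
        assert conv.kind == "convergent"

    def test_disjoint_regions_give_empty_with_diagnostic(self):
        r1 = build_sector_annulus(ORIGIN, _track(345.0, bearing=0.0))
        r2 = build_sector_annulus(ORIGIN, _track(345.0, bearing=180.0, hornet="Z"))
        conv = intersect_regions([r1, r2])
        assert conv.is_empty
        assert "no convergence" in conv.diagnostic

    def test_intersection_never_larger(self):
        r1, r2 = self._two_overlapping()
        conv = intersect_regions([r1, r2])
        assert not conv.is_empty
        assert conv.area_m2 <= min(r1.area_m2, r2.area_m2)
        assert set(conv.provenance) == {("BS1", "YB"), ("BS2", "YB")}

    def test_commutative_and_associative(self):
        r1, r2 = self._two_overlapping()
        r3 = build_sector_annulus(
            PointLocal(-300.0, 540.0), _track(345.0, bearing=90.0, station="BS3")
        )
        a = intersect_regions([r1, r2, r3]).area_m2
        b = intersect_regions([r3, r1, r2]).area_m2
        c = intersect_regions([intersect_regions([r2, r3]), r1]).area_m2
        assert b == pytest.approx(a, rel=1e-6)
        assert c == pytest.approx(a, rel=1e-6)

    def test_frame_mismatch_rejected(self):
        r1 = build_sector_annulus(ORIGIN, _track(345.0), frame="A")
        r2 = build_sector_annulus(ORIGIN, _track(345.0, hornet="Z"), frame="B")
        with pytest.raises(FrameMismatchError):
            intersect_regions([r1, r2])

    def test_needs_two_regions(self):
        r1 = build_sector_annulus(ORIGIN, _track(345.0))
        with pytest.raises(ValidationError):
            intersect_regions([r1])


class TestContainment:
    def test_mid_band_point_contained(self):
        region = build_sector_annulus(ORIGIN, _track(345.0, bearing=0.0))
        assert containment_check(region, PointLocal(0.0, 540.0))  # (270+810)/2

    def test_apex_excluded_by_annulus(self):
        region = build_sector_annulus(ORIGIN, _track(345.0))
        assert not containment_check(region, ORIGIN)

    def test_centroid_of_single_region_contained(self):
        region = build_sector_annulus(ORIGIN, _track(345.0, bearing=120.0))
        c = region.polygon.centroid
        assert containment_check(region, PointLocal(c.x, c.y))

    def test_boundary_point_on_true_arc_contained(self):
        # exact outer-arc point between two discretisation vertices
        region = build_sector_annulus(ORIGIN, _track(345.0, bearing=0.0))
        ang = math.radians(0.5)
        p = PointLocal(810.0 * math.sin(ang), 810.0 * math.cos(ang))
        assert containment_check(region, p)


class TestSecondStation:
    def test_contract(self):
        region = build_sector_annulus(ORIGIN, _track(345.0, bearing=40.0))
        margin = 50.0
        p = suggest_second_station(region, margin)
        pt = Point(p.x, p.y)
        assert not region.polygon.contains(pt)
        assert margin <= region.polygon.distance(pt) <= 2 * margin

    def test_deterministic(self):
        region = build_sector_annulus(ORIGIN, _track(345.0, bearing=40.0))
        assert suggest_second_station(region, 50.0) == suggest_second_station(region, 50.0)

    def test_empty_region_rejected(self):
        r1 = build_sector_annulus(ORIGIN, _track(345.0, bearing=0.0))
        r2 = build_sector_annulus(ORIGIN, _track(345.0, bearing=180.0, hornet="Z"))
        empty = intersect_regions([r1, r2])
        with pytest.raises(ValidationError):
            suggest_second_station(empty, 50.0)


class TestLocalize:
    def test_pairwise_only_across_stations(self):
        stations = {"BS1": ORIGIN, "BS2": PointLocal(400.0, 540.0)}
        tracks = [
            _track(345.0, bearing=0.0, station="BS1", hornet="A"),
            _track(345.0, bearing=5.0, station="BS1", hornet="B"),
            _track(345.0, bearing=270.0, station="BS2", hornet="C"),
        ]
        result = localize(stations, tracks)
        assert len(result.single_regions) == 3
        # BS1xBS2 pairs only: (A,C) and (B,C), never (A,B)
        assert len(result.pairwise_convergent) == 2
        assert result.full_convergent is not None

    def test_unknown_station_rejected(self):
        with pytest.raises(ValidationError):
            localize({"BS1": ORIGIN}, [_track(345.0, station="BS9")])
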