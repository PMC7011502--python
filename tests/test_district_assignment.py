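"""Point location, methods A/B/C, counting tables and district merging."""

import math

import numpy as np
import pytest
from scipy import integrate

from geomaskd.district_assignment import (
    AssignmentA,
    AssignmentError,
    AssignmentSingle,
    DistrictMap,
    GeometryError,
    assign_method_A,
    assign_method_B,
    assign_method_C,
    count_clusters_per_district,
    locate_point,
    merge_districts,
)
from geomaskd.geomask_sim import ClusterRecord, GeoPoint, SimConfig
from geomaskd.synthetic_data import DEG_KM

import shapely


def _cluster(lon, lat, urban=False, cid="c1"):
    return ClusterRecord(
        cluster_id=cid, point=GeoPoint(lon=lon, lat=lat), urban=urban, stratum_id="s", weight=1.0
    )


def _ray_cast(poly_coords, x, y):
    """Independent crossing-number point-in-polygon (open boundary)."""
    inside = False
    n = len(poly_coords)
    for i in range(n - 1):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[i + 1]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x_cross > x:
                inside = not inside
    return inside


class TestLocatePoint:
    def test_interior_and_outside(self, toy_rect_map):
        assert locate_point(toy_rect_map, GeoPoint(lon=0.5, lat=0.5)) == "R00"
        assert locate_point(toy_rect_map, GeoPoint(lon=5.0, lat=5.0)) is None

    def test_shared_edge_goes_to_smallest_id(self, toy_rect_map):
        # (1, 0.5) lies on the R00|R01 edge; (0.5, 1) on R00|R10
        assert locate_point(toy_rect_map, GeoPoint(lon=1.0, lat=0.5)) == "R00"
        assert locate_point(toy_rect_map, GeoPoint(lon=0.5, lat=1.0)) == "R00"

    def test_agrees_with_ray_casting_oracle(self, toy_rect_map, rng):
        coords = {
            d: list(toy_rect_map.geometries[d].exterior.coords)
            for d in toy_rect_map.district_ids
        }
        for _ in range(1000):
            x, y = rng.uniform(-0.5, 2.5), rng.uniform(-0.5, 2.5)
            expected = None
            for d in sorted(coords):
                if _ray_cast(coords[d], x, y):
                    expected = d
                    break
            assert locate_point(toy_rect_map, GeoPoint(lon=x, lat=y)) == expected


class TestMethodA:
    def test_far_from_boundary_is_whole(self, grid_map):
        # center of the middle district: boundaries ~15 km away, cap 5 km
        center = grid_map.geometries["D1_1"].centroid
        cl = _cluster(center.x, center.y)
        a = assign_method_A(cl, grid_map, SimConfig(n_sims=500, seed=2))
        assert a.proportions == {"D1_1": 1.0}

    def test_proportions_sum_to_one(self, grid_map, rng):
        minx, miny, maxx, maxy = shapely.unary_union(
            list(grid_map.geometries.values())
        ).bounds
        for i in range(10):
            cl = _cluster(rng.uniform(minx, maxx), rng.uniform(miny, maxy), cid=f"c{i}")
            a = assign_method_A(cl, grid_map, SimConfig(n_sims=300, seed=4))
            assert abs(sum(a.proportions.values()) - 1.0) < 1e-9

    def test_boundary_symmetry(self, two_district_map):
        # cluster exactly on the long straight boundary between the two cells
        boundary_lon = two_district_map.geometries["D0_0"].bounds[2]
        lat_mid = (
            two_district_map.geometries["D0_0"].bounds[1]
            + two_district_map.geometries["D0_0"].bounds[3]
        ) / 2.0
        cl = _cluster(boundary_lon, lat_mid)
        a = assign_method_A(cl, two_district_map, SimConfig(n_sims=1000, seed=11))
        assert set(a.proportions) == {"D0_0", "D0_1"}
        for p in a.proportions.values():
            assert abs(p - 0.5) < 0.05

    def test_matches_halfplane_arc_integral(self, two_district_map):
        # cluster a km west of a straight boundary, rural cap 5 km: the
        # chance a displacement crosses is (1/(2 pi d)) * int_a^d 2 acos(a/r) dr
        a_km = 2.0
        d_max = 5.0
        bounds = two_district_map.geometries["D0_0"].bounds
        boundary_lon = bounds[2]
        lat_mid = (bounds[1] + bounds[3]) / 2.0
        lon = boundary_lon - a_km / (DEG_KM * math.cos(math.radians(lat_mid)))
        cl = _cluster(lon, lat_mid)
        assign = assign_method_A(cl, two_district_map, SimConfig(n_sims=5000, seed=8))
        p_cross_oracle = integrate.quad(
            lambda r: 2.0 * math.acos(a_km / r), a_km, d_max
        )[0] / (2.0 * math.pi * d_max)
        assert abs(assign.proportions.get("D0_1", 0.0) - p_cross_oracle) < 0.02

    def test_all_points_outside_raises(self, toy_rect_map):
        cl = _cluster(10.0, 10.0)
        with pytest.raises(AssignmentError):
            assign_method_A(cl, toy_rect_map, SimConfig(n_sims=50, seed=1))

    def test_outside_points_renormalized(self, toy_rect_map):
        # cluster near the map corner: many draws fall off-map but the
        # returned proportions always renormalize over landed points
        cl = _cluster(0.01, 0.01, urban=False)
        a = assign_method_A(cl, toy_rect_map, SimConfig(n_sims=500, seed=6))
        assert abs(sum(a.proportions.values()) - 1.0) < 1e-9


class TestMethodB:
    def test_picks_largest_proportion(self, toy_rect_map):
        # four candidate districts with shares 0.13 / 0.24 / 0.33 / 0.29
        # (printed rounded shares renormalized to sum exactly to 1): the
        # modal district wins even though the released point sits elsewhere
        raw = {"R00": 0.13, "R01": 0.24, "R10": 0.33, "R11": 0.29}
        total = sum(raw.values())
        a = AssignmentA(
            cluster_id="c", proportions={d: p / total for d, p in raw.items()}
        )
        b = assign_method_B(a, GeoPoint(lon=1.5, lat=0.5), toy_rect_map)
        assert b.district_id == "R10" and b.method == "B"

    def test_degenerate_single_district(self, toy_rect_map):
        a = AssignmentA(cluster_id="c", proportions={"R11": 1.0})
        assert assign_method_B(a, GeoPoint(lon=1.5, lat=1.5), toy_rect_map).district_id == "R11"

    def test_tie_prefers_district_of_geomasked_point(self, toy_rect_map):
        a = AssignmentA(cluster_id="c", proportions={"R00": 0.5, "R01": 0.5})
        assert (
            assign_method_B(a, GeoPoint(lon=1.5, lat=0.5), toy_rect_map).district_id == "R01"
        )
        # geomasked point outside the tied set: smallest id wins
        assert (
            assign_method_B(a, GeoPoint(lon=0.5, lat=1.5), toy_rect_map).district_id == "R00"
        )

    def test_b_is_argmax_of_a(self, grid_map, rng):
        minx, miny, maxx, maxy = shapely.unary_union(list(grid_map.geometries.values())).bounds
        for i in range(10):
            cl = _cluster(rng.uniform(minx, maxx), rng.uniform(miny, maxy), cid=f"b{i}")
            a = assign_method_A(cl, grid_map, SimConfig(n_sims=200, seed=3))
            b = assign_method_B(a, cl.point, grid_map)
            assert a.proportions[b.district_id] == max(a.proportions.values())


class TestMethodC:
    def test_contains_geomasked_point(self, toy_rect_map):
        assert assign_method_C(_cluster(1.5, 0.5), toy_rect_map).district_id == "R01"

    def test_snap_offshore_point(self, grid_map):
        # ~0.2 km west of the map's west edge snaps to the nearest district
        bounds = grid_map.geometries["D0_0"].bounds
        lat_mid = (bounds[1] + bounds[3]) / 2.0
        lon = bounds[0] - 0.2 / (DEG_KM * math.cos(math.radians(lat_mid)))
        assert assign_method_C(_cluster(lon, lat_mid), grid_map).district_id == "D0_0"

    def test_too_far_raises(self, grid_map):
        bounds = grid_map.geometries["D0_0"].bounds
        lon = bounds[0] - 2.0 / DEG_KM
        with pytest.raises(AssignmentError):
            assign_method_C(_cluster(lon, bounds[1]), grid_map)


class TestCounting:
    def test_method_a_whole_and_partial(self):
        assigns = [
            AssignmentA(cluster_id="c1", proportions={"D1": 1.0}),
            AssignmentA(cluster_id="c2", proportions={"D1": 1.0}),
            AssignmentA(cluster_id="c3", proportions={"D1": 1.0}),
            AssignmentA(cluster_id="c4", proportions={"D1": 0.6, "D2": 0.4}),
        ]
        tab = count_clusters_per_district(assigns, "A").set_index("district_id")
        assert tab.loc["D1", "whole"] == 3 and tab.loc["D1", "partial"] == 1
        assert tab.loc["D2", "whole"] == 0 and tab.loc["D2", "partial"] == 1

    def test_single_assignment_counts(self):
        assigns = [
            AssignmentSingle(cluster_id=c, district_id=d, method="C")
            for c, d in [("c1", "D1"), ("c2", "D1"), ("c3", "D2")]
        ]
        tab = count_clusters_per_district(assigns, "C").set_index("district_id")
        assert tab.loc["D1", "count"] == 2 and tab.loc["D2", "count"] == 1


class TestMergeDistricts:
    def test_merge_two_into_one(self, toy_rect_map):
        merged = merge_districts(toy_rect_map, {"R01": "R00"})
        assert len(merged) == 3
        expected = toy_rect_map.geometries["R00"].area + toy_rect_map.geometries["R01"].area
        assert abs(merged.geometries["R00"].area - expected) < 1e-12

    def test_exclusion(self, toy_rect_map):
        assert len(merge_districts(toy_rect_map, exclusions={"R11"})) == 3

    def test_identity(self, toy_rect_map):
        out = merge_districts(toy_rect_map)
        assert out.district_ids == toy_rect_map.district_ids

    def test_unknown_id_raises(self, toy_rect_map):
        with pytest.raises(ValueError):
            merge_districts(toy_rect_map, {"nope": "R00"})


def test_overlapping_districts_rejected():
    with pytest.raises(GeometryError):
        DistrictMap(
            [
                ("A", "A", shapely.box(0, 0, 1, 1)),
                ("B", "B", shapely.box(0.5, 0, 1.5, 1)),
            ]
        )


def test_duplicate_ids_rejected():
    with pytest.raises(GeometryError):
        DistrictMap(
            [("A", "A", shapely.box(0, 0, 1, 1)), ("A", "A2", shapely.box(2, 0, 3, 1))]
        )
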