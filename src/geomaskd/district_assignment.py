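"""Assignment of geomasked clusters to districts by methods A, B and C.

Method A re-displaces the released coordinate ``n_sims`` times and assigns
each district the fraction of simulated locations falling inside it — a
fractional assignment summing to 1. Method B picks the modal district of
those simulations. Method C simply locates the released coordinate itself.

Polygons are treated as planar shapes in lon/lat, which is standard at
ADM2 scale away from the antimeridian. Boundary points count as inside
(closed polygons); a point on a shared boundary goes to the district with
the lexicographically smallest id, so :func:`locate_point` is a total
function on the union of the districts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import nearest_points, unary_union
from shapely.strtree import STRtree

from geomaskd.geomask_sim import (
    ClusterRecord,
    GeoPoint,
    SimConfig,
    geodesic_km,
    simulate_cluster_locations,
)

DEFAULT_SNAP_TOLERANCE_KM = 0.5


class GeometryError(ValueError):
    """Raised when boundary geometry violates the district-map invariants."""


class AssignmentError(ValueError):
    """Raised when a cluster cannot be assigned to any district."""


@dataclass(frozen=True)
class AssignmentA:
    """Fractional (method A) assignment: district -> share of simulated points."""

    cluster_id: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"cluster {self.cluster_id}: proportions sum to {total}, expected 1"
            )
        if any(p <= 0 for p in self.proportions.values()):
            raise ValueError("proportions must be strictly positive")


@dataclass(frozen=True)
class AssignmentSingle:
    """Single-district assignment (method B or C)."""

    cluster_id: str
    district_id: str
    method: Literal["B", "C"]


class DistrictMap:
    """A partition of a study area into uniquely-identified district polygons.

    Parameters
    ----------
    districts
        Iterable of ``(district_id, name, geometry)``; geometries are
        shapely (Multi)Polygons in WGS84 lon/lat.
    validate
        Check validity and pairwise interior-disjointness (on by default).

    Districts are held sorted by id so that boundary tie-breaks are
    deterministic.
    """

    def __init__(
        self,
        districts: Iterable[tuple[str, str, BaseGeometry]],
        *,
        validate: bool = True,
    ) -> None:
        entries = sorted(((str(d), str(n), g) for d, n, g in districts), key=lambda t: t[0])
        ids = [d for d, _, _ in entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GeometryError(f"duplicate district ids: {dupes}")
        if validate:
            self._validate(entries)
        self.district_ids: list[str] = ids
        self.names: dict[str, str] = {d: n for d, n, _ in entries}
        self.geometries: dict[str, BaseGeometry] = {d: g for d, _, g in entries}
        self._geoms = [g for _, _, g in entries]
        self._tree = STRtree(self._geoms)

    @staticmethod
    def _validate(entries: Sequence[tuple[str, str, BaseGeometry]]) -> None:
        for d, _, g in entries:
            if g.geom_type not in ("Polygon", "MultiPolygon"):
                raise GeometryError(f"district {d}: non-polygonal geometry {g.geom_type}")
            if not g.is_valid:
                raise GeometryError(f"district {d}: invalid polygon geometry")
        # pairwise interior-disjoint: overlapping interiors have positive
        # intersection area (shared boundaries do not)
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                gi, gj = entries[i][2], entries[j][2]
                if gi.intersects(gj):
                    inter = gi.intersection(gj)
                    if inter.area > 1e-12:
                        raise GeometryError(
                            f"districts {entries[i][0]} and {entries[j][0]} overlap"
                        )

    def __len__(self) -> int:
        return len(self.district_ids)

    def __contains__(self, district_id: str) -> bool:
        return district_id in self.geometries

    def locate_many(self, lons: np.ndarray, lats: np.ndarray) -> list[str | None]:
        """Vectorized point location with the smallest-id boundary tie-break."""
        pts = shapely.points(lons, lats)
        pt_idx, geom_idx = self._tree.query(pts, predicate="covered_by")
        best: dict[int, int] = {}
        for p, g in zip(pt_idx.tolist(), geom_idx.tolist()):
            if p not in best or g < best[p]:  # geoms sorted by id
                best[p] = g
        return [
            self.district_ids[best[i]] if i in best else None for i in range(len(pts))
        ]


def locate_point(district_map: DistrictMap, point: GeoPoint) -> str | None:
    """District containing ``point``, or None if outside every polygon.

    Boundary points count as inside; on a shared boundary the smallest
    district id (lexicographic) wins.
    """
    return district_map.locate_many(np.array([point.lon]), np.array([point.lat]))[0]


def _snap_to_map(district_map: DistrictMap, point: GeoPoint, tolerance_km: float) -> str | None:
    """Nearest district within ``tolerance_km`` geodesic distance, else None."""
    p = shapely.Point(point.lon, point.lat)
    best_id, best_km = None, math.inf
    for d in district_map.district_ids:
        g = district_map.geometries[d]
        near = nearest_points(g, p)[0]
        km = geodesic_km(GeoPoint(lon=near.x, lat=near.y), point)
        if km < best_km:
            best_id, best_km = d, km
    return best_id if best_km <= tolerance_km else None


def assign_method_A(
    cluster: ClusterRecord, district_map: DistrictMap, config: SimConfig
) -> AssignmentA:
    """Fractional assignment from geomask-inversion simulations.

    Each district's proportion is the count of simulated points it
    contains, divided by the count landing in *any* district: points
    falling outside the map (sea, a neighboring country) cannot be the
    true origin and are dropped with renormalization.
    """
    points = simulate_cluster_locations(cluster, config)
    lons = np.array([p.lon for p in points])
    lats = np.array([p.lat for p in points])
    located = district_map.locate_many(lons, lats)
    counts: dict[str, int] = {}
    for d in located:
        if d is not None:
            counts[d] = counts.get(d, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise AssignmentError(
            f"cluster {cluster.cluster_id}: all {config.n_sims} simulated points "
            "fell outside every district"
        )
    return AssignmentA(
        cluster_id=cluster.cluster_id,
        proportions={d: c / total for d, c in sorted(counts.items())},
    )


def assign_method_B(
    assignment_a: AssignmentA,
    geomasked_point: GeoPoint,
    district_map: DistrictMap,
) -> AssignmentSingle:
    """Modal district of the simulations (largest method-A proportion).

    Ties go to the district containing the released point if it is among
    the tied set (consistent with method C), else to the smallest id.
    """
    max_p = max(assignment_a.proportions.values())
    tied = sorted(d for d, p in assignment_a.proportions.items() if p == max_p)
    if len(tied) > 1:
        home = locate_point(district_map, geomasked_point)
        district = home if home in tied else tied[0]
    else:
        district = tied[0]
    return AssignmentSingle(cluster_id=assignment_a.cluster_id, district_id=district, method="B")


def assign_method_C(
    cluster: ClusterRecord,
    district_map: DistrictMap,
    *,
    snap_tolerance_km: float = DEFAULT_SNAP_TOLERANCE_KM,
) -> AssignmentSingle:
    """District containing the released geomasked coordinate.

    A point outside every polygon (e.g. just offshore after digitization
    slack) is snapped to the nearest district within ``snap_tolerance_km``;
    beyond that an :class:`AssignmentError` is raised.
    """
    district = locate_point(district_map, cluster.point)
    if district is None:
        district = _snap_to_map(district_map, cluster.point, snap_tolerance_km)
    if district is None:
        raise AssignmentError(
            f"cluster {cluster.cluster_id}: geomasked point ({cluster.point.lon}, "
            f"{cluster.point.lat}) is farther than {snap_tolerance_km} km from every district"
        )
    return AssignmentSingle(cluster_id=cluster.cluster_id, district_id=district, method="C")


def count_clusters_per_district(
    assignments: Sequence[AssignmentA] | Sequence[AssignmentSingle],
    method: Literal["A", "B", "C"],
) -> pd.DataFrame:
    """Cluster counts per district.

    Methods B/C give one integer ``count`` column. Method A gives two:
    ``whole`` (clusters whose entire displacement disc sits in the
    district, proportion exactly 1) and ``partial`` (clusters with more
    than one possible district of origin, 0 < proportion < 1).
    """
    if method == "A":
        whole: dict[str, int] = {}
        partial: dict[str, int] = {}
        for a in assignments:
            if not isinstance(a, AssignmentA):
                raise TypeError("method A expects AssignmentA records")
            for d, p in a.proportions.items():
                if p == 1.0:
                    whole[d] = whole.get(d, 0) + 1
                else:
                    partial[d] = partial.get(d, 0) + 1
        ids = sorted(set(whole) | set(partial))
        return pd.DataFrame(
            {
                "district_id": ids,
                "whole": [whole.get(d, 0) for d in ids],
                "partial": [partial.get(d, 0) for d in ids],
            }
        )
    counts: dict[str, int] = {}
    for a in assignments:
        if not isinstance(a, AssignmentSingle) or a.method != method:
            raise TypeError(f"expected AssignmentSingle records from method {method}")
        counts[a.district_id] = counts.get(a.district_id, 0) + 1
    ids = sorted(counts)
    return pd.DataFrame({"district_id": ids, "count": [counts[d] for d in ids]})


def merge_districts(
    district_map: DistrictMap,
    merge_spec: Mapping[str, str] | None = None,
    exclusions: Iterable[str] = (),
) -> DistrictMap:
    """Merge and/or drop districts (e.g. combine two, exclude an island).

    ``merge_spec`` maps old ids onto the id they are absorbed into; merged
    polygons are unions and keep the target's name. ``exclusions`` removes
    districts outright. Unknown ids raise.
    """
    merge_spec = dict(merge_spec or {})
    exclusions = set(exclusions)
    known = set(district_map.district_ids)
    unknown = (set(merge_spec) | set(merge_spec.values()) | exclusions) - known
    if unknown:
        raise ValueError(f"unknown district ids: {sorted(unknown)}")

    target_of = {d: merge_spec.get(d, d) for d in district_map.district_ids}
    groups: dict[str, list[str]] = {}
    for d in district_map.district_ids:
        if d in exclusions:
            continue
        groups.setdefault(target_of[d], []).append(d)
    entries = []
    for target, members in groups.items():
        geom = (
            district_map.geometries[members[0]]
            if len(members) == 1
            else unary_union([district_map.geometries[m] for m in members])
        )
        entries.append((target, district_map.names[target], geom))
    return DistrictMap(entries)
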