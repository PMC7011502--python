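"""Synthetic country, survey design and indicator data with known truth.

Emulates the structure of a DHS-like survey on a gridded country so the
assignment and estimation pipeline can be exercised end to end with a
known answer key:

* a rectangular grid of districts (edge lengths may vary by row, giving a
  spread of district areas);
* clusters placed uniformly at random inside their true district, each
  urban or rural, stratified by district x urban/rural, with sampling
  weights equal to the inverse within-district sampling fraction;
* three binary coverage indicators with district-level true prevalences
  and cluster-level heterogeneity on the logit scale: y ~ Bernoulli(
  invlogit(logit(prev_d) + u_c)), u_c ~ Normal(0, cluster_sd^2);
* per-household eligibility thinning that reproduces the precision
  hierarchy of real coverage indicators — every household reports a
  water-type indicator, about 70% have an under-5 child (stunting-type),
  and about 12% have an infant aged 0-5 months (breastfeeding-type);
* the geomask displacement applied to the true cluster locations, with an
  option to redraw until the displaced point stays inside the true
  district (the post-2009 DHS protocol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely

from geomaskd.district_assignment import DistrictMap, locate_point
from geomaskd.geomask_sim import (
    ClusterRecord,
    GeoPoint,
    cluster_rng,
    draw_displacement,
    offset_point,
)
from geomaskd.survey_estimation import IndicatorRecord

DEG_KM = math.pi * 6371.0088 / 180.0  # km per degree of great-circle arc

DEFAULT_INDICATORS = ("water", "stunting", "breastfeeding")
# Eligibility: fraction of households contributing to each indicator
DEFAULT_ELIGIBILITY = {"water": 1.0, "stunting": 0.7, "breastfeeding": 0.12}
# Ranges the default district prevalences are drawn from, per indicator
DEFAULT_PREVALENCE_RANGE = {
    "water": (0.02, 0.25),
    "stunting": (0.30, 0.65),
    "breastfeeding": (0.20, 0.80),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic country and survey.

    ``cell_km`` is a single edge length or one per grid row (varying row
    heights/widths mimic the wide spread of real district areas).
    ``prevalence`` maps indicator -> district_id -> true proportion; if
    omitted, prevalences are drawn per district from indicator-specific
    ranges using ``seed``. ``cluster_sd`` is the logit-scale SD of the
    between-cluster random effect. Weights are inverse within-district
    sampling fractions computed from a notional household density.
    """

    grid_nx: int = 5
    grid_ny: int = 5
    cell_km: float | Sequence[float] = 30.0
    clusters_per_district: int = 20
    households_per_cluster: int = 25
    urban_fraction: float = 0.2
    prevalence: Mapping[str, Mapping[str, float]] | None = None
    cluster_sd: float = 0.4
    missing_rate: float | Mapping[str, float] = 0.0
    seed: int = 0
    d_max_urban_km: float = 2.0
    d_max_rural_km: float = 5.0
    origin_lon: float = 34.0
    origin_lat: float = -15.0
    eligibility: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ELIGIBILITY))
    household_density_per_km2: float = 40.0

    def __post_init__(self) -> None:
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.clusters_per_district < 1 or self.households_per_cluster < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValueError("urban_fraction must be in [0, 1]")

    def row_cell_km(self) -> list[float]:
        if np.isscalar(self.cell_km):
            return [float(self.cell_km)] * self.grid_ny
        cells = [float(c) for c in self.cell_km]  # type: ignore[union-attr]
        if len(cells) != self.grid_ny:
            raise ValueError("cell_km sequence must have one entry per grid row")
        return cells

    def missing_rate_for(self, indicator: str) -> float:
        if isinstance(self.missing_rate, Mapping):
            return float(self.missing_rate.get(indicator, 0.0))
        return float(self.missing_rate)


@dataclass
class SyntheticTruth:
    """The answer key: true cluster locations/districts and true prevalences."""

    cluster_location: dict[str, GeoPoint]
    cluster_district: dict[str, str]
    district_prevalence: dict[str, dict[str, float]]  # indicator -> district -> p


def generate_country(config: SyntheticConfig) -> DistrictMap:
    """Build a grid of rectangular districts in lon/lat around the origin.

    Row r has grid_nx districts of edge ``cell_km[r]``; km are converted
    to degrees at the row's central latitude so cells are approximately
    square on the ground. District ids are ``D<row>_<col>``.
    """
    rows = config.row_cell_km()
    entries = []
    lat0 = config.origin_lat
    for r, edge_km in enumerate(rows):
        dlat = edge_km / DEG_KM
        lat_mid = lat0 + dlat / 2.0
        dlon = edge_km / (DEG_KM * math.cos(math.radians(lat_mid)))
        for c in range(config.grid_nx):
            did = f"D{r}_{c}"
            box = shapely.box(
                config.origin_lon + c * dlon,
                lat0,
                config.origin_lon + (c + 1) * dlon,
                lat0 + dlat,
            )
            entries.append((did, did, box))
        lat0 += dlat
    return DistrictMap(entries)


def _uniform_point_in(geom, rng: np.random.Generator) -> GeoPoint:
    minx, miny, maxx, maxy = geom.bounds
    for _ in range(10000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if geom.covers(shapely.Point(x, y)):
            return GeoPoint(lon=x, lat=y)
    raise RuntimeError("failed to sample a point inside the district")


def _draw_prevalences(
    district_map: DistrictMap, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for ind in DEFAULT_INDICATORS:
        lo, hi = DEFAULT_PREVALENCE_RANGE[ind]
        out[ind] = {d: float(rng.uniform(lo, hi)) for d in district_map.district_ids}
    return out


def generate_survey(
    district_map: DistrictMap, config: SyntheticConfig
) -> tuple[list[ClusterRecord], dict[str, list[IndicatorRecord]], SyntheticTruth]:
    """Draw clusters, households and indicator outcomes with known truth.

    Returns ``(clusters, indicators, truth)`` where the clusters carry
    their TRUE (pre-geomask) locations, ``indicators`` maps indicator
    name to household-level records, and ``truth`` is the answer key.
    Strata are district x urban/rural. Each household's weight is the
    inverse of the district's sampling fraction against a notional
    household count proportional to district area.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0xFFFFFFFF, 0x5EED]))
    if config.prevalence is not None:
        prevalences = {k: dict(v) for k, v in config.prevalence.items()}
    else:
        prevalences = _draw_prevalences(district_map, rng)
    indicator_names = list(prevalences)

    clusters: list[ClusterRecord] = []
    indicators: dict[str, list[IndicatorRecord]] = {ind: [] for ind in indicator_names}
    truth = SyntheticTruth(
        cluster_location={}, cluster_district={}, district_prevalence=prevalences
    )

    for d in district_map.district_ids:
        geom = district_map.geometries[d]
        # approximate ground area in km^2 from the lon/lat box
        minx, miny, maxx, maxy = geom.bounds
        area_km2 = (
            (maxx - minx) * DEG_KM * math.cos(math.radians((miny + maxy) / 2.0))
        ) * ((maxy - miny) * DEG_KM)
        n_sampled = config.clusters_per_district * config.households_per_cluster
        notional_households = max(n_sampled, area_km2 * config.household_density_per_km2)
        weight = notional_households / n_sampled  # inverse sampling fraction

        for ci in range(config.clusters_per_district):
            cid = f"{d}_c{ci}"
            loc = _uniform_point_in(geom, rng)
            urban = bool(rng.uniform() < config.urban_fraction)
            stratum = f"{d}:{'urban' if urban else 'rural'}"
            clusters.append(
                ClusterRecord(
                    cluster_id=cid, point=loc, urban=urban, stratum_id=stratum, weight=weight
                )
            )
            truth.cluster_location[cid] = loc
            truth.cluster_district[cid] = d

            for ind in indicator_names:
                p_d = prevalences[ind][d]
                if 0.0 < p_d < 1.0:
                    u_c = rng.normal(0.0, config.cluster_sd)
                    p_c = 1.0 / (1.0 + math.exp(-(math.log(p_d / (1 - p_d)) + u_c)))
                else:
                    p_c = p_d
                elig = float(config.eligibility.get(ind, 1.0))
                miss = config.missing_rate_for(ind)
                for h in range(config.households_per_cluster):
                    if rng.uniform() >= elig:
                        continue
                    y: int | None = int(rng.uniform() < p_c)
                    if miss > 0 and rng.uniform() < miss:
                        y = None
                    indicators[ind].append(
                        IndicatorRecord(
                            cluster_id=cid,
                            record_id=f"{cid}_h{h}",
                            stratum_id=stratum,
                            base_weight=weight,
                            y=y,
                        )
                    )
    return clusters, indicators, truth


def apply_geomask(
    clusters: Sequence[ClusterRecord],
    config: SyntheticConfig,
    constrain_within_district: bool = False,
    *,
    district_map: DistrictMap | None = None,
    true_districts: Mapping[str, str] | None = None,
    max_redraws: int = 1000,
) -> list[ClusterRecord]:
    """Displace each cluster's true location once by the geomask model.

    If ``district_map`` is given, displacements landing outside the
    country (the union of districts) are redrawn — released DHS
    coordinates always fall inside the surveyed country. With
    ``constrain_within_district`` (the post-2009 DHS protocol) the
    displacement is instead redrawn until the masked point stays inside
    the cluster's true district, which needs ``true_districts`` as well.
    Both redraw loops are capped at ``max_redraws`` attempts. The
    displacement stream is derived from (config.seed, cluster_id) with a
    salt distinct from the inversion-simulation stream.
    """
    if constrain_within_district and (district_map is None or true_districts is None):
        raise ValueError("constrained geomasking needs district_map and true_districts")
    country = (
        shapely.unary_union(list(district_map.geometries.values()))
        if district_map is not None
        else None
    )
    masked: list[ClusterRecord] = []
    for cl in clusters:
        rng = cluster_rng(config.seed, f"geomask:{cl.cluster_id}")
        cap = config.d_max_urban_km if cl.urban else config.d_max_rural_km
        point = None
        for _ in range(max_redraws):
            draw = draw_displacement(rng, cap)
            candidate = offset_point(cl.point, draw)
            if constrain_within_district:
                if locate_point(district_map, candidate) == true_districts[cl.cluster_id]:
                    point = candidate
                    break
            elif country is None or country.covers(shapely.Point(candidate.lon, candidate.lat)):
                point = candidate
                break
        if point is None:
            raise RuntimeError(
                f"cluster {cl.cluster_id}: no within-district displacement in "
                f"{max_redraws} redraws"
            )
        masked.append(
            ClusterRecord(
                cluster_id=cl.cluster_id,
                point=point,
                urban=cl.urban,
                stratum_id=cl.stratum_id,
                weight=cl.weight,
            )
        )
    return masked
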