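"""District-level coverage estimation under the complex survey design.

A coverage indicator is a weighted proportion p̂ = Σwy / Σw over the
records assigned to a district. Because the weights are themselves random
under the design, p̂ is a ratio estimator; its variance is obtained by
Taylor linearization with survey clusters as primary sampling units (PSUs)
nested in strata:

    z_k  = w_k (y_k − p̂) / Ŵ            (linearized score per record)
    z_hc = Σ_{k in cluster c} z_k        (cluster totals)
    V    = Σ_h  n_h/(n_h − 1)  Σ_c (z_hc − z̄_h)²

with n_h the number of clusters in stratum h within the district and z̄_h
the stratum mean of cluster totals. No finite-population correction is
applied (the usual DHS convention).

Confidence intervals default to the logit-transformed Wald form with a t
critical value on df = (#clusters − #strata) degrees of freedom, which
keeps intervals inside [0, 1]; at p̂ exactly 0 or 1 the logit interval is
undefined and the estimate is flagged not estimable. A plain Wald interval
is available via ``ci_method="wald"``.

Method A's fractional assignments enter through the weights: a record in a
cluster with district share p_d contributes to district d with weight
p_d × base_weight, keeping its original cluster and stratum for variance
purposes. Across districts, each record's adjusted weights sum exactly to
its base weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from geomaskd.district_assignment import AssignmentA, AssignmentSingle


@dataclass(frozen=True)
class IndicatorRecord:
    """One household/individual observation of a binary indicator.

    ``y`` is 0, 1, or None (missing; dropped listwise per indicator).
    """

    cluster_id: str
    record_id: str
    stratum_id: str
    base_weight: float
    y: int | None

    def __post_init__(self) -> None:
        if not self.base_weight > 0:
            raise ValueError(f"record {self.record_id}: base_weight must be positive")
        if self.y is not None and self.y not in (0, 1):
            raise ValueError(f"record {self.record_id}: y must be 0, 1 or None")


@dataclass
class DistrictRecordSet:
    """The records contributing to one district's estimate.

    ``records`` rows are (stratum_id, cluster_id, adjusted_weight, y).
    Under methods B/C adjusted_weight equals the base weight; under
    method A it is the base weight times the cluster's district share.
    """

    district_id: str
    records: list[tuple[str, str, float, int]]


@dataclass(frozen=True)
class DistrictEstimate:
    """A weighted proportion with design-based uncertainty for one district."""

    district_id: str
    indicator: str
    p_hat: float
    se: float
    ci_low: float | None
    ci_high: float | None
    n_clusters: int
    n_obs: int
    df: int

    @property
    def ci_estimable(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None


def build_district_records(
    indicators: Sequence[IndicatorRecord],
    assignments: Sequence[AssignmentA] | Sequence[AssignmentSingle],
    method: Literal["A", "B", "C"],
) -> list[DistrictRecordSet]:
    """Distribute indicator records over districts according to an assignment.

    Methods B/C place each record in its cluster's single district with
    its base weight. Method A replicates the record into every district
    with positive share, scaling the weight by the share. Missing ``y``
    are dropped. A record whose cluster has no assignment raises.
    """
    if method == "A":
        shares: dict[str, Mapping[str, float]] = {}
        for a in assignments:
            if not isinstance(a, AssignmentA):
                raise TypeError("method A expects AssignmentA records")
            shares[a.cluster_id] = a.proportions
        out: dict[str, DistrictRecordSet] = {}
        for rec in indicators:
            if rec.y is None:
                continue
            if rec.cluster_id not in shares:
                raise ValueError(f"cluster {rec.cluster_id} has no assignment")
            for d, p in shares[rec.cluster_id].items():
                rs = out.setdefault(d, DistrictRecordSet(district_id=d, records=[]))
                rs.records.append(
                    (rec.stratum_id, rec.cluster_id, p * rec.base_weight, rec.y)
                )
        return [out[d] for d in sorted(out)]

    where: dict[str, str] = {}
    for a in assignments:
        if not isinstance(a, AssignmentSingle):
            raise TypeError(f"method {method} expects AssignmentSingle records")
        where[a.cluster_id] = a.district_id
    out = {}
    for rec in indicators:
        if rec.y is None:
            continue
        if rec.cluster_id not in where:
            raise ValueError(f"cluster {rec.cluster_id} has no assignment")
        d = where[rec.cluster_id]
        rs = out.setdefault(d, DistrictRecordSet(district_id=d, records=[]))
        rs.records.append((rec.stratum_id, rec.cluster_id, rec.base_weight, rec.y))
    return [out[d] for d in sorted(out)]


def taylor_variance(
    strata: np.ndarray, clusters: np.ndarray, weights: np.ndarray, y: np.ndarray
) -> tuple[float, float, int, int]:
    """Linearized variance of the weighted proportion.

    Returns (p_hat, variance, n_clusters, n_strata). Strata with a single
    cluster use the "centered" singleton rule: the lone cluster total is
    deviated about the grand mean of all cluster totals, with factor 1 —
    the conservative convention common in survey software.
    """
    w_total = float(weights.sum())
    p_hat = float((weights * y).sum() / w_total)
    z = weights * (y - p_hat) / w_total

    df_z = pd.DataFrame({"stratum": strata, "cluster": clusters, "z": z})
    cluster_totals = df_z.groupby(["stratum", "cluster"], sort=False)["z"].sum()
    n_clusters = len(cluster_totals)
    per_stratum = cluster_totals.groupby(level="stratum", sort=False)
    n_strata = per_stratum.ngroups
    grand_mean = float(cluster_totals.mean())

    variance = 0.0
    for _, totals in per_stratum:
        vals = totals.to_numpy()
        n_h = len(vals)
        if n_h == 1:
            variance += float((vals[0] - grand_mean) ** 2)
        else:
            variance += n_h / (n_h - 1) * float(((vals - vals.mean()) ** 2).sum())
    return p_hat, variance, n_clusters, n_strata


def estimate_proportion(
    recordset: DistrictRecordSet,
    *,
    indicator: str = "",
    level: float = 0.95,
    ci_method: Literal["logit", "wald"] = "logit",
) -> DistrictEstimate:
    """Estimate a district's coverage proportion with Taylor-linearized SE.

    Raises on an empty record set. At p̂ exactly 0 or 1 the CI is flagged
    not estimable (``ci_low``/``ci_high`` = None), matching the behavior
    of standard survey software at degenerate proportions.
    """
    if not recordset.records:
        raise ValueError(f"district {recordset.district_id}: empty record set")
    strata = np.array([r[0] for r in recordset.records])
    clusters = np.array([r[1] for r in recordset.records])
    weights = np.array([r[2] for r in recordset.records], dtype=float)
    y = np.array([r[3] for r in recordset.records], dtype=float)
    if np.any(weights <= 0):
        raise ValueError("adjusted weights must be positive")

    p_hat, variance, n_clusters, n_strata = taylor_variance(strata, clusters, weights, y)
    se = math.sqrt(max(variance, 0.0))
    df = n_clusters - n_strata
    n_obs = len(y)

    ci_low: float | None
    ci_high: float | None
    if p_hat in (0.0, 1.0) or se == 0.0:
        # CI not estimable at degenerate proportions; at se == 0 the
        # interval collapses to the point
        if p_hat in (0.0, 1.0):
            ci_low = ci_high = None
        else:
            ci_low = ci_high = p_hat
    else:
        t_crit = stats.t.ppf(0.5 + level / 2.0, df) if df >= 1 else math.inf
        if ci_method == "logit":
            logit_p = math.log(p_hat / (1.0 - p_hat))
            half = t_crit * se / (p_hat * (1.0 - p_hat))
            lo, hi = logit_p - half, logit_p + half
            ci_low = 1.0 / (1.0 + math.exp(-lo))
            ci_high = 1.0 / (1.0 + math.exp(-hi))
        else:
            ci_low = max(0.0, p_hat - t_crit * se)
            ci_high = min(1.0, p_hat + t_crit * se)
        if math.isinf(t_crit):
            ci_low = ci_high = None

    return DistrictEstimate(
        district_id=recordset.district_id,
        indicator=indicator,
        p_hat=p_hat,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_clusters=n_clusters,
        n_obs=n_obs,
        df=df,
    )


def _round_half_up_percent(p: float) -> int:
    """Round a proportion to an integer percent, halves away from zero."""
    return int(math.floor(100.0 * p + 0.5))


def estimate_change(est_t1: DistrictEstimate, est_t2: DistrictEstimate) -> int:
    """Between-survey change in percentage points, on rounded integer percents.

    Public coverage tables print integer percents; change is computed on
    those rounded values (round(100 p̂_t2) − round(100 p̂_t1)) so it matches
    the printed columns exactly.
    """
    if est_t1.district_id != est_t2.district_id:
        raise ValueError("change requires the same district at both time points")
    if est_t1.indicator != est_t2.indicator:
        raise ValueError("change requires the same indicator at both time points")
    return _round_half_up_percent(est_t2.p_hat) - _round_half_up_percent(est_t1.p_hat)


def estimates_to_frame(estimates: Sequence[DistrictEstimate]) -> pd.DataFrame:
    """Tabulate estimates; not-estimable CI bounds become NaN."""
    return pd.DataFrame(
        {
            "district_id": [e.district_id for e in estimates],
            "indicator": [e.indicator for e in estimates],
            "p_hat": [e.p_hat for e in estimates],
            "se": [e.se for e in estimates],
            "ci_low": [e.ci_low if e.ci_low is not None else np.nan for e in estimates],
            "ci_high": [e.ci_high if e.ci_high is not None else np.nan for e in estimates],
            "n_clusters": [e.n_clusters for e in estimates],
            "n_obs": [e.n_obs for e in estimates],
            "df": [e.df for e in estimates],
        }
    )
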