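# geomaskd

Assign geomasked household-survey clusters to second-order administrative
districts, and estimate district-level coverage indicators under the complex
survey design.

## The problem

Household surveys such as the DHS release the GPS centroid of each survey
cluster only after **geomasking**: the point is displaced by a random bearing
(uniform on [0, 2π)) and a random distance (uniform on [0, *d*max], with
*d*max = 2 km in urban and 5 km in rural areas). Before 2009 this displacement
could carry a cluster's released coordinate across a district boundary, so
district-level (ADM2) estimates built by naively locating released points can
attribute households to the wrong district.

`geomaskd` implements three assignment rules and everything downstream of
them:

* **Method A** — invert the geomask by Monte Carlo. Re-apply the displacement
  model to the released point *n* times (default 1000) and give each district
  the fraction of simulated locations it contains: a fractional assignment
  {*d* : *p_d*} with Σ *p_d* = 1. Each household record then enters district
  *d* with weight *p_d* · *w*, the product of the district likelihood and the
  cluster's sampling weight.
* **Method B** — the modal district of those simulations (single district).
* **Method C** — the district whose polygon contains the released point
  itself (single district; simplest to implement).

District coverage is the weighted proportion p̂ = Σ*wy*/Σ*w*, with
Taylor-linearized variance treating clusters as PSUs within strata

V(p̂) = Σ_h n_h/(n_h−1) Σ_c (z_hc − z̄_h)², z_hc = Σ_{k∈c} w_k(y_k − p̂)/Ŵ,

and logit-scale confidence intervals on *t* with df = clusters − strata
(flagged not estimable at p̂ ∈ {0, 1}). Agreement between two vectors of
district estimates is quantified with Lin's concordance correlation
coefficient ρ_c = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with a Fisher-z interval.

A synthetic-data module generates a gridded country, a DHS-like stratified
cluster design, three indicators with a realistic precision hierarchy
(household / under-5 child / infant level), and the geomask itself — so every
method can be validated against a known answer key without any restricted
survey data.

## Worked example

```python
from geomaskd import *
from geomaskd.synthetic_data import SyntheticConfig, generate_country, \
    generate_survey, apply_geomask
from geomaskd.agreement import ccc_confidence_interval
from geomaskd.survey_estimation import estimates_to_frame

cfg = SyntheticConfig(grid_nx=4, grid_ny=4, cell_km=15.0,
                      clusters_per_district=12, households_per_cluster=20,
                      seed=11)
dmap = generate_country(cfg)                      # 16 districts, 15 km cells
clusters, indicators, truth = generate_survey(dmap, cfg)
masked = apply_geomask(clusters, cfg, district_map=dmap)

sim = SimConfig(n_sims=1000, seed=11)
a = assign_method_A(masked[3], dmap, sim)
print(a.proportions)
```

```
{'D0_0': 0.781, 'D1_0': 0.219}
```

This cluster sits close enough to a boundary that 21.9% of the 1000 simulated
origins fall in the neighboring district; methods B and C both pick `D0_0`,
which here is also the true district. Estimating the household-level
indicator by method C and comparing with estimates from the true assignments:

```python
c_list = [assign_method_C(c, dmap) for c in masked]
ests = [estimate_proportion(rs, indicator="water")
        for rs in build_district_records(indicators["water"], c_list, "C")]
print(estimates_to_frame(ests).head(4).to_string(index=False))
```

```
district_id indicator    p_hat       se   ci_low  ci_high  n_clusters  n_obs  df
       D0_0     water 0.100000 0.027273 0.052351 0.182659          11    220   8
       D0_1     water 0.172727 0.031496 0.111580 0.257665          11    220   8
       D0_2     water 0.065385 0.014310 0.039560 0.106204          13    260   9
       D0_3     water 0.105000 0.029351 0.054008 0.194250          10    200   8
```

Each row is one district: the weighted coverage proportion, its
design-based standard error, the 95% logit CI, and how many clusters and
households inform it (note `n_clusters` differs from the 12 sampled per
district — geomasking moved some clusters across boundaries). Agreement with
the truth-based estimates across the 16 districts:

```
CCC method C vs truth: 0.975 (95% CI 0.930-0.991, n=16)
```

i.e. even with every cluster geomasked, simple point-in-polygon assignment
recovers the district-level coverage pattern almost perfectly at this
district size.

## Command line

```bash
geomaskd synth --seed 3 --out-dir data/          # synthetic country + survey
geomaskd simulate --clusters data/clusters.csv --n-sims 1000 --seed 3 --out sims.csv
geomaskd assign --boundaries data/boundaries.geojson --clusters data/clusters.csv \
                --method all --seed 3 --out assignments.csv
geomaskd estimate --assignments assignments.csv --clusters data/clusters.csv \
                  --indicators data/indicators.csv --method C --out estimates.csv
geomaskd agree --x estimates.csv --y estimates_truth.csv
geomaskd run --config run.yaml                   # the whole pipeline
```

Boundaries are GeoJSON (WGS84 lon/lat); clusters and indicators are plain
CSV; all distances are km and coordinates are always (lon, lat).

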