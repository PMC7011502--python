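# Methods

## Displacement model

The geomask displaces a cluster centroid by an independent pair
(bearing, distance): bearing ~ Uniform[0, 2π), measured clockwise from north,
and distance ~ Uniform[0, d_max] with d_max = 2 km (urban) or 5 km (rural).
The distance is uniform *in distance*; its areal density is proportional to
1/r, so displaced points concentrate near the origin rather than spreading
evenly over the disc. An area-uniform variant (distance = d_max·√U) is
available behind `SimConfig(area_uniform=True)` for sensitivity analysis only.
The rare rural long-displacement rule (with probability 0.01 the cap is
10 km) is implemented behind `include_one_percent_rule` and off by default:
at a 1% rate it has negligible effect on district assignment and the default
matches the displacement model the rest of the package inverts. Draw order
(bearing-then-distance vs the reverse) is irrelevant for independent draws.

Because the displacement distribution is symmetric under reflection through
the displaced point, re-applying the same model to a *released* coordinate
samples the possible true origins (a flat spatial prior over the disc of
radius d_max). That is what `simulate_cluster_locations` does, and what
methods A and B consume.

## Coordinates and geometry

Offsets use the spherical-earth forward-bearing formula with
R = 6371.0088 km (IUGG mean radius). At geomasking scales (≤ 10 km) the
discrepancy against a full ellipsoidal geodesic is well under 0.1%, far below
the resolution of any ADM2 boundary polygon; the closed form is deterministic
and testable against one-degree-arc and inverse-bearing oracles. Offsets are
refused within 1° of the poles (the bearing formula degenerates) and beyond
150 km (far outside the regime the model describes).

Polygons are treated as planar shapes in lon/lat — standard at district
scale; longitudes near ±180° are not supported. Point-in-polygon membership
is closed (boundary counts as inside) and a point on a shared boundary
resolves to the lexicographically smallest district id, making `locate_point`
a deterministic total function on the union of districts.

## Assignment rules and their edge cases

* Simulated points falling outside every district (sea, a neighboring
  country) are dropped and method A's proportions renormalized over points
  that landed somewhere: the true origin must lie in *some* district, so
  renormalization is the maximum-likelihood treatment under the displacement
  model. A cluster whose simulated points all fall off-map is an error, not
  a silent zero.
* Method B ties: broken in favor of the district containing the released
  point if it is among the tied set (consistent with method C), else the
  smallest district id. Ties at n_sims = 1000 are rare but must be
  deterministic.
* Method C snaps an off-map released point to the nearest district within
  0.5 km (GPS noise plus polygon digitization slack; configurable); beyond
  that it errors.
* District merging takes polygon unions; exclusions drop the district.
  Clusters that become unassignable after an exclusion are dropped from the
  pipeline with a logged warning — their data leave the analysis exactly as
  an excluded district's clusters should.

## Survey estimation

The coverage estimator is the ratio p̂ = Σwy/Σw. Its Taylor-linearized
variance uses cluster totals of the score z_k = w_k(y_k − p̂)/Ŵ within
strata, with the n_h/(n_h − 1) small-sample factor and no finite-population
correction (the DHS convention). Design degrees of freedom are
clusters − strata.

Choices where survey software conventions differ:

* **CI form.** Default is the logit-transformed Wald interval with a t
  critical value, which stays inside [0, 1] and is undefined at p̂ ∈ {0, 1} —
  those estimates are flagged "not estimable" rather than given a degenerate
  interval. A plain (symmetric, clipped) Wald interval is available with
  `ci_method="wald"`.
* **Singleton strata.** After disaggregation to districts, a district ×
  stratum cell often contains a single cluster, making the within-stratum
  variance term undefined. The default is the conservative "centered" rule:
  the lone cluster total deviates about the grand mean of all cluster totals
  in the district, with factor 1.
* **Method A records** keep their original cluster and stratum for variance
  purposes and carry adjusted weight p_d·w; the same physical cluster may
  therefore contribute (fractionally) to several districts. Across districts
  the adjusted weights of a record sum to its base weight exactly.
* **Missingness** is listwise per indicator.
* **Rounding.** Estimates are carried at full precision; public-table change
  between two surveys is computed on rounded integer percents
  (round(100·p̂₂) − round(100·p̂₁), halves away from zero) so the change
  column always matches the printed point-estimate columns.

## Agreement

Lin's concordance correlation coefficient uses biased (divide-by-n) moments,
per the original definition; an (n−1) variant is behind a flag. The interval
is the standard construction: Fisher z-transform of ρ̂_c, Lin's asymptotic
variance of the transformed estimate, normal quantiles, tanh back-transform.
Exact agreement (|ρ̂_c| = 1) has no finite z-variance and is returned flagged
degenerate. Tests check the attenuation property |ρ_c| ≤ |r|, a coverage
simulation at n = 26 pairs, and overlap with a jackknife interval.

## Synthetic data: what it emulates, and what it does not

The generator builds a rectangular grid of districts (not Voronoi cells):
areas are controllable — edge lengths may vary by row to mimic the order-of-
magnitude spread of real district areas — and straight boundaries admit
closed-form oracles (the half-plane crossing probability
(2πd)⁻¹∫ 2·arccos(a/r) dr is tested against method A directly).

The survey design mirrors DHS practice: strata are district × urban/rural,
clusters are uniform within their district, and weights are inverse
within-district sampling fractions against a notional household count
proportional to district area (density 40 households/km²). Outcomes follow a
logit-normal cluster effect: y ~ Bernoulli(invlogit(logit(prev_d) + u_c)),
u_c ~ N(0, cluster_sd²) with cluster_sd = 0.4 by default — moderate
between-cluster heterogeneity of the kind cluster surveys are designed
around. The three default indicators reproduce the precision hierarchy of
real coverage measures by eligibility thinning: every household reports the
household-level indicator, 70% have an under-5 child, 12% have an infant
aged 0–5 months. Default district prevalences are drawn per indicator from
ranges chosen to span low-coverage (household water, 2–25%), mid
(stunting-like, 30–65%) and wide (breastfeeding-like, 20–80%) regimes.

`apply_geomask` displaces each true location once. When given the district
map it redraws displacements that leave the country — released survey
coordinates always fall inside the surveyed country — and with
`constrain_within_district=True` it redraws until the point stays in its true
district (the post-2009 protocol), capped at 1000 redraws.

What the generator does **not** emulate: population rasters (clusters are
uniform in area, not population-weighted), non-response patterns beyond
simple missingness, urban/rural prevalence gradients, or real geography.
Passing recovery tests therefore show that the assignment and estimation
machinery is correct under the stated displacement model — not that any
particular real survey would achieve the same agreement.

## Randomness and determinism

Every cluster's simulation stream is a generator seeded from
(global seed, SHA-256(cluster id)), so results are independent of processing
order and of Python hash randomization; the geomasking stream uses a salted
cluster id so it never collides with the inversion stream. All pipeline
outputs are byte-identical under a repeated seed.

## Problem sizes

The validation experiments use a 5×5 country with 30 km districts, 20
clusters per district and 25 households per cluster (500 clusters, 12,500
households) for parameter recovery, and a 12 km-cell variant where geomask
ambiguity is common for the method-comparison experiment; 1000 geomask
inversions per cluster throughout. These sizes give Monte-Carlo error well
below every tolerance asserted while keeping the whole suite and the
acceptance script in the seconds-to-minutes range.

At district edges comparable to the rural displacement cap, the fractional
method's agreement with truth tends to sit at or below the single-district
methods' — fractional reallocation smears cluster-level heterogeneity across
districts, which hurts most for the sparse infant-level indicator — but at
these problem sizes the three methods' CCCs are within a few hundredths and
the ranking can invert between seeds; the comparison is reported, not gated.

## Known limitations

* No population weighting of candidate districts in method A (a flat prior
  over the displacement disc).
* No small-area smoothing or modelling of the resulting estimates.
* Planar polygon handling breaks at the antimeridian.
* Shapefile input is not supported; convert boundaries to GeoJSON first.
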