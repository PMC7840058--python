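# Methods

## Statistical model

Each behavior type (caching, foraging, nesting, ...) is modeled separately
as a case-control contrast between its used locations and a set of control
plots drawn from the available landscape:

```
y_i ~ Bernoulli(p_i),   logit p_i = β₀ + βᵀ x_i + u_{r(i)},   u_r ~ N(0, σ²)
```

with `x_i` the z-scored habitat attributes (a 0/1 disturbance indicator
enters unstandardized), `r(i)` the study region, and `u_r` a region-level
random intercept absorbing regional differences in baseline use intensity.
Under case-control sampling with a low used:control ratio, `exp(β_k)` is an
approximation to the resource selection function for attribute `k`; the
intercept reflects the sampling ratio, not an absolute use probability.

### Permutation allocation of controls

Fitting several behavior models against the same control pool would reuse
each control observation several times and understate uncertainty. Instead,
for each of `n_perm` permutations the controls are partitioned **within
each region** among the behavior types, with set sizes fixed by
largest-remainder apportionment proportional to the region's behavior
frequencies (so sizes are identical across permutations and only
membership varies), and membership a uniform random partition. A region
whose behavior count is zero contributes no controls to that behavior, so
each behavior's model spans exactly the regions where it was observed.
Largest-remainder apportionment is exact for the design this package was
built around: 81 controls split over behavior counts {32, 19} gives
{51, 30}; 53 over {26, 22, 28} gives {18, 15, 20}; 212 over {12, 12}
gives {106, 106}.

### Fitting: Laplace marginal likelihood

The random intercepts are integrated out with a Laplace approximation.
For fixed `(β, σ²)` the conditional mode `û_r` of each region solves a
one-dimensional concave problem (damped Newton, warm-started between
objective evaluations); the approximate marginal log-likelihood is

```
ℓ(β, σ²) = Σ_i [y_i η_i − log(1+e^{η_i})] − Σ_r û_r²/(2σ²) − ½ Σ_r log(1 + σ² W_r)
```

with `W_r = Σ_{i∈r} μ_i(1−μ_i)` at the mode. `(β, σ²)` is maximized by
L-BFGS-B with `σ² ∈ [0, 25]`; the `σ² = 0` boundary is a valid solution
(it reduces exactly to ordinary logistic regression, which the tests
verify against an independent IRLS fit). The coefficient covariance is the
inverse Schur complement of the joint `(β, u)` information, the same
quantity glmer-style software reports. A fit is discarded (the permutation
is "unreasonable") if the optimizer fails, coefficients diverge beyond
|β| > 50 on the z-scale (apparent complete separation), the information
matrix is singular, or a behavior receives fewer controls than it has
parameters.

### Pooling, significance, random effects, accuracy

One coefficient vector is drawn from `N(β̂, Cov β̂)` per retained
permutation (covariances failing positive semi-definiteness by more than
round-off are eigenvalue-clipped to the nearest PSD matrix, with a
warning). The pooled draws therefore mix estimation uncertainty with
control-allocation uncertainty. Per coefficient the report gives the
pooled mean, the sd of the draws as its standard error, and the
empirical-CDF two-tailed probability

```
p = min(1, 2·min(#{draws ≤ 0}, #{draws ≥ 0}) / n_draws)
```

whose resolution is `2/n_draws`; no distributional form is assumed. The
exact type-I level of this doubled-tail procedure is characterized by the
null-calibration simulations rather than asserted. Random effects are
summarized by the across-permutation mean and sd of each region's
conditional mode and by the fraction of retained permutations whose
estimated variance sits at the boundary (σ̂² < 10⁻⁶ on the z-scale counts
as a "zero-value" random effect). Model quality is within-sample
classification accuracy at threshold 0.5 (ties count as incorrect),
including the region intercepts in the prediction by default, averaged
over retained permutations; no held-out validation is attempted.

Reproducibility: allocation and each behavior's draw sequence run on
independent sub-streams of one seed, so a run is bit-reproducible and a
behavior's results do not depend on which other behaviors are fit.

## Preprocessing chain

* **Unit normalization** — elevation feet → meters (× 0.3048); ordinal
  distance-to-road classes → class-midpoint km through a configurable map
  (an example FIA-style map ships for tests; survey dialects differ, so
  the map is a required input for real class-coded data). Conversion is
  idempotent: the attribute registry tracks current units.
* **Spatial averaging** — within each (behavior, region) group, the
  closest pair of used locations under the threshold is replaced by its
  unweighted centroid, repeating until all pairs are separated; ties break
  on the lexicographically smallest record-id pair, making the result
  deterministic and row-order invariant. The default threshold is the
  smallest center separation preventing overlap of two circular habitat
  plots, `2·sqrt(A/π)` = 71.8 m for 0.405-ha plots. Distances are computed
  on planar meters; lon/lat input is projected through a local
  equirectangular projection (adequate at ≤ 100 km extents; a UTM
  projection can be substituted through the same callable interface).
  The pipeline averages the merged records' habitat attributes unweighted,
  matching the coordinate treatment.
* **Collinearity screen** — pairwise Pearson |r| on complete cases;
  pairs at or above the threshold (default 0.65) drop the lower-priority
  member, with direct field measurements prioritized over derived indices
  (so e.g. a stand-density index correlated with tree cover is the one
  removed). Zero-variance attributes are dropped as degenerate.
* **Woody-debris collapse** — the seven size-class counts are z-scored
  and replaced by their first principal component, oriented so that more
  debris gives larger scores; the component's variance fraction is
  reported.
* **Standardization** — pooled z-transformation (sample sd, n−1) across
  all regions and roles; scaling is stored for inversion. An option
  standardizes on control-only statistics instead, which reads
  coefficients on the availability distribution's scale (used by the
  recovery simulations).
* **Distance to edge** — signed shortest Euclidean distance to the
  ecotone polyline; the sign comes from a declared woodland-side
  convention of the directed line (inferring the side from elevation
  would require information the geometry alone does not carry). Used for
  visualization only, never as a model covariate.
* **Missing data** — missing cells are preserved on ingest; each
  downstream operation drops the records incomplete for the attributes it
  uses and logs the count (complete-case analysis; no imputation).

## Ordination

PCA via SVD of the centered, z-scored attribute matrix over the included
records (by default all controls plus used locations of the modeled
behaviors; rare behaviors excluded by the validation threshold stay out).
Variance fractions are eigenvalue shares; eigenvector signs are resolved
by anchoring a chosen attribute (default: the largest-|loading| attribute
per component) to a non-negative loading, flipping scores consistently.
Group centroids are arithmetic means of scores on the first two
components.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, and is the
basis of every end-to-end test:

* per region, control attributes are multivariate normal with a realistic
  correlation structure (tree cover vs stand density index r = 0.68, a
  canopy/tree/age block, and a woody-debris block correlated at 0.84 so
  the seven classes' first PC carries ~86% of their variation), truncated
  to valid ranges (covers to [0, 100], counts to ≥ 0);
* used locations are a weighted sample **without replacement** (via
  exponential/Gumbel keys) from a ≥ 10× availability pool, with weight
  `exp(u_r + βᵀ z(x))`, `z` standardized by the pool's own statistics.
  Because used and control attributes come from the same distribution,
  the case-control logistic contrast identifies exactly the generating β,
  making recovery a well-defined test of the full pipeline. Truncation
  happens before weighting, so β is defined on the truncated scale;
* region intercepts `u_r ~ N(0, σ²)` redistribute each behavior's total
  count across regions (multinomial over baseline shares × `exp(u_r)`);
  with σ = 0 the configured counts are exact;
* coordinates track elevation so that selection for low elevation pulls
  used locations toward a synthetic woodland–shrubland ecotone polyline;
  a controllable fraction of used points is placed within the 71.8-m
  merge threshold of a neighbor to exercise spatial averaging; missing
  cells are injected at a configurable rate (default 2% per cell);
* the study-shaped default reproduces the motivating design: three
  Great Basin regions with control pools of 212/81/53 and per-region
  behavior counts caching 12/32/26, foraging 0/19/22, nesting 12/0/28,
  plus a 3-location roosting group that the validation step flags.

What it does **not** emulate: spatial autocorrelation of habitat,
movement/home-range structure among used points, non-Gaussian attribute
marginals (beyond truncation), observation error in attributes, or
informative missingness. Passing tests therefore demonstrate correctness
of the estimator under its own assumptions, not robustness to violations
real field data may show.

## Numerical choices

* Optimizer: L-BFGS-B, `ftol` 1e-11 / `gtol` 1e-7, up to 500 iterations;
  inner Newton for the modes stops at step < 1e-10 with steps clipped to
  ±5. Warm starts chain along consecutive permutations of a behavior.
* Boundary detection: σ̂² < 1e-6 (z-scaled covariates make this a
  negligible intercept spread).
* Quantile convention in box-plot summaries: linear interpolation between
  order statistics, recorded in the output metadata; optional truncation
  bounds are recorded rather than applied.
* Every output table carries the run seed and a hash of the analytic
  configuration (the output directory is excluded from the hash so
  identical analyses are byte-identical wherever they are written).

## Problem sizes

The default inference profile is 10,000 permutations. The test suite and
the acceptance script use scaled profiles chosen for tight feedback:
recovery simulations run 3–5 replicates of a ~2,400-record, three-region,
two-behavior study at 200 permutations; null calibration runs 6–8
replicates of a ~1,300-record study at 50 permutations; the study-shaped
demonstration runs 150–200 permutations. Pooled-draw summaries at 200
permutations resolve p-values to 0.01, ample for the checks performed.

## Known limitations

* The Laplace approximation is least accurate for few regions with few
  observations; with only 2–3 regions σ² is weakly identified and often
  boundary — this mirrors the behavior of glmer-type fits on the same
  designs and is surfaced through the zero-variance fraction.
* Complete-case handling can discard a substantial share of records when
  per-cell missingness is spread over many attributes; the dropped counts
  are logged per stage.
* The merge step's greedy closest-pair agglomeration is one reasonable
  reading of "spatially average nearby locations"; other groupings
  (e.g. single-linkage clusters merged at once) would differ on dense
  clusters.
* p-values from pooled draws are granular at `2/n_retained` and cannot be
  smaller than that.
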