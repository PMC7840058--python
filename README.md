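# rsfperm

Behavior-specific habitat-selection analysis for used/control site tables:
PCA ordination plus a permutation-allocated, case-control, random-intercept
logistic procedure whose exponentiated coefficients approximate a resource
selection function (RSF).

## The problem

Wildlife habitat studies often contrast *used* locations (where animals
were observed caching, foraging, nesting, ...) against *control* plots
sampled from the available landscape — a case-control, used–available
design. When several behavior types are modeled against one shared control
pool, reusing the same controls in every model inflates Type I error.
`rsfperm` implements the alternative: in each of many permutations the
control sites are partitioned region by region among the behavior types in
proportion to behavior frequency, each behavior's model is refit on its
allocated controls, and results are pooled across permutations so that
every control informs every model exactly once per permutation.

The per-permutation model is a binomial mixed model

```
logit P(used_i) = β₀ + βᵀ x_i + u_region(i),   u_r ~ N(0, σ²)
```

fit by maximum likelihood with a Laplace approximation to the marginal
likelihood (σ² = 0 boundary fits are valid and tracked). From each retained
fit one coefficient vector is drawn from `N(β̂, Cov(β̂))`; the pooled draws
carry both estimation and allocation uncertainty. Significance of each
coefficient is the empirical-CDF two-tailed probability: twice the smaller
of the fractions of pooled draws at or below / at or above zero. Because
used locations are rare relative to controls, `exp(β)` approximates the
RSF; the intercept does not estimate overall use probability.

Around this core the package provides the full pipeline: site-table
reading and validation, unit normalization (feet → meters, ordinal
road-distance classes → midpoint km), spatial averaging of same-behavior
locations closer than the plot-overlap threshold (71.8 m for 0.405-ha
circular plots), collinearity screening, PCA collapse of the seven
woody-debris size classes, pooled z-scoring, signed distance to a
woodland–shrubland ecotone polyline, PCA ordination with oriented loadings
and group centroids, and box-plot summary tables. A synthetic-data
generator reproduces the statistical structure the analysis assumes
(three regions, correlated habitat attributes, log-linear selection,
region-level intercept heterogeneity, missing cells), so every stage is
testable without field data.

## Worked example

Generate a study-shaped synthetic dataset and run the whole pipeline:

```bash
rsf simulate --seed 7 --out demo
# wrote 500 records to demo/site_table.tsv

printf 'synthetic: true\nseed: 7\nn_perm: 200\nout_dir: demo/out\n' > demo/cfg.yaml
rsf run --config demo/cfg.yaml
# outputs written to demo/out
#   caching: 200/200 retained, accuracy 0.840
#   foraging: 200/200 retained, accuracy 0.770
#   nesting: 200/200 retained, accuracy 0.878
```

The provenance log shows the auditable filtering trail:

```
generate_study: seed=7, 346 controls, 154 used locations, sigma=1.0
convert_units: elevation ft -> m (x0.3048)
merge_close_locations: 154 used locations -> 137 at threshold 71.8 m
screen_attributes: retained [...]; dropped {'canopy_cover': '|r| = 0.69 with tree_cover',
                                            'stand_density_index': '|r| = 0.69 with tree_cover'}
collapse_woody_debris: 7 classes -> 'woody_debris', first PC describes 85.5% of variation
```

and `demo/out/inference_caching.tsv` holds the pooled summary (excerpt):

```
term                  term_type  mean    se     p
intercept             fixed     -2.091  0.860  0.01
slope                 fixed     -0.925  0.347  0.00
tree_cover            fixed     -1.200  0.424  0.00
distance_to_road      fixed     -0.703  0.301  0.02
disturbance_presence  fixed      1.790  0.699  0.01
```

Read: caching-type use declines with slope, tree cover, and distance to
road and rises with recent disturbance — each `exp(mean)` is the RSF odds
multiplier per standard deviation of the attribute, and `p` is the pooled
two-tailed tail mass at zero. These match the selection coefficients this
synthetic dataset was generated with (the generator's "truth" is echoed to
`demo/truth.json`).

Library use mirrors the CLI:

```python
from rsfperm.pipeline import RunConfig, run_pipeline
result = run_pipeline(RunConfig(synthetic=True, seed=7, n_perm=200, out_dir="demo/out"))
result.inference["caching"].fixed_summary     # mean / se / p per coefficient
result.ordination.variance_fractions          # PCA variance shares
```

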