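# nichecentroid

Range-wide abundance estimation from the **distance to the ecological
niche centroid** (DNC), as applied to the Bolson tortoise (*Gopherus
flavomarginatus*) of the Chihuahuan Desert. The package is aimed at
spatial ecologists who have presence records, a handful of abundance
plots and a stack of environmental rasters, and want a defensible
range-wide abundance map with uncertainty attached.

## The method

The ecological-niche-centroid hypothesis holds that a species' local
abundance peaks where the environment is closest to the multivariate
mean of its suitable conditions and decays toward the niche edge. The
pipeline operationalizes this in four steps:

1. **Niche model.** From the environmental vectors at n occurrence
   points, estimate the centroid μ (per-variable mean) and covariance Σ.
   Every pixel's suitability is its Mahalanobis distance
   d(v) = √((v−μ)ᵀ Σ⁻¹ (v−μ)), which is unitless, affine-invariant and
   robust to the strong collinearity of bioclimatic layers
   (near-singular Σ is ridge-regularized). The **potential
   distribution** is the envelope d ≤ d_max, where d_max is the distance
   of the farthest occurrence; steep-slope pixels can optionally be
   excluded.
2. **Abundance–distance curve.** Plot counts y (burrows/km²) are
   regressed on d through nine classic curve-estimation families
   (linear, logarithmic, inverse, quadratic, cubic, power, growth,
   exponential, logistic), each fitted by OLS in its linearizing space;
   the family with the highest adjusted R² = 1 − (1−R²)(n−1)/(n−p−1)
   wins. For the tortoise survey (n = 22 plots) this is the inverse law
   y = b₀ + b₁/d.
3. **Projection.** The best-fit curve is evaluated on every pixel of the
   potential distribution, giving the range-wide abundance surface.
4. **Validation and uncertainty.** Repeated 70/30 splits score the
   model by regressing observed on predicted held-out abundance
   (reported as mean R² over 10 trials); a 1000-iteration 65/35
   split-resampling scheme yields per-pixel standard-deviation and 95%
   band surfaces for the uncertainty map plus a held-out coverage
   percentage. Percent-decline arithmetic compares historical and
   recent census counts.

A first-class synthetic module generates seeded virtual species
(autocorrelated landscapes, center-weighted occurrences, Poisson plot
counts from a known inverse law) so every stage is testable end to end
without downloading rasters.

## Worked example

```python
import numpy as np
import nichecentroid as nc

# simulate a virtual species with a known inverse abundance law
cfg = nc.SyntheticConfig(n_rows=120, n_cols=120, seed=7)
bundle = nc.simulate(cfg)

# estimate the niche from the sampled occurrences
occ_env, _ = nc.extract_values(bundle.stack, bundle.occurrences)
model = nc.fit_niche(occ_env, variable_names=bundle.stack.layer_names)
nc.envelope_radius(model, occ_env)
surf = nc.distance_surface(model, bundle.stack)
mask = nc.potential_distribution(surf, model.d_max)

# relate plot counts to distance-to-centroid and pick the best family
plot_env, kept = nc.extract_values(bundle.stack, bundle.plots)
d = np.array([nc.mahalanobis(model, row) for row in plot_env])
y = bundle.plots.counts.astype(float)
fits = nc.fit_all(d, y)
print(nc.fits_report(fits))
best = nc.select_best(fits)

# project and validate
amap = nc.abundance_surface(best, surf, mask)
report = nc.split_validate(d, y, best.family, seed=7)
unc = nc.bootstrap_uncertainty(d, y, best.family, distance_surface=surf,
                               mask=mask, n_iterations=1000, seed=7)
```

This prints the goodness-of-fit table

```
Model             R2  adj R2   P-value
inverse        0.900   0.895   < 0.001
quadratic      0.905   0.895   < 0.001
cubic          0.909   0.894   < 0.001
logarithmic    0.874   0.868   < 0.001
power          0.843   0.836   < 0.001
logistic       0.809   0.799   < 0.001
growth         0.809   0.799   < 0.001
exponential    0.809   0.799   < 0.001
linear         0.762   0.750   < 0.001
```

and the inverse family is selected (`best.family == "inverse"`), correctly
recovering the generating law's form. `report.mean_r2` comes out at 0.768
(sd 0.228) — the predictive R² of the refit model on held-out plots — and
`unc.coverage_pct` at 92.5%, the share of held-out observations inside
their 95% regression interval. Note how the quadratic and cubic fits sit
within a hair of the inverse: at 22 plots the families are genuinely hard
to tell apart, which is exactly why the validation machinery matters.

The packaged field survey is available as
`nc.mapimi_burrow_counts()` (22 localities, 1–20 burrows/km²), and
`nc.percent_decline(88, 8)` reproduces the 91% census decline recorded at
Cerros Emilio.

A command-line interface wraps both halves:

```bash
nichecentroid simulate --seed 4 --out sim/          # virtual species to disk
nichecentroid run --raster sim/env_00.asc --raster sim/env_01.asc \
    --raster sim/env_02.asc --raster sim/env_03.asc \
    --occurrences sim/occurrences.csv --plots sim/plots.csv --out out/
```

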