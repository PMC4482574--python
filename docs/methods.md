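# Methods

## Model and assumptions

The pipeline estimates range-wide abundance from a single premise: a
species' expected local density is a decreasing function of the
Mahalanobis distance between a site's environment and the niche
centroid. Three assumptions follow and shape every design choice:

* the occurrence sample is representative enough that its multivariate
  mean and covariance describe the realized niche (no attempt is made to
  correct sampling bias beyond an optional one-point-per-cell thinning);
* suitability is unimodal and elliptical in environmental space — the
  Mahalanobis metric cannot represent multimodal or strongly skewed
  niches;
* plot counts are conditionally independent given distance, so ordinary
  least squares in each curve family's linearizing space is a sensible
  estimator and split-based validation is meaningful.

Distances use the root (not squared) Mahalanobis form; the squared form
is available via `NicheModel.squared` for sensitivity work, and every
downstream step is agnostic to the choice because the curve families are
refit against whichever scale is supplied.

## Niche estimation numerics

Bioclimatic layers are strongly collinear, so the sample covariance of
occurrence environments is routinely near-singular. When its condition
number exceeds 1e10 a ridge ε·mean(diag(Σ))·I is added, with ε starting
at 1e-8 and escalating tenfold until the matrix inverts
(`regularization_used` is flagged; a pseudo-inverse is the last resort).
Zero-variance variables go through the same path with a warning naming
the variable, rather than failing hard on degenerate inputs. The
envelope threshold is inclusive (d ≤ d_max), so all fitting occurrences
lie inside the potential distribution by construction. No slope cutoff
is applied unless the user supplies one: steep-terrain exclusion is a
biological judgement we refuse to default.

Points map to raster cells by the half-open convention
[x0, x0+cs) × (y0−cs, y0], which makes boundary assignment deterministic
and means a shift smaller than half a cell never changes the cell.
Points on nodata cells or off-grid are dropped and reported, never
silently imputed. All layers must share grid geometry and CRS exactly;
the package performs no reprojection or resampling.

## Curve estimation conventions

Each family is fitted by OLS after its classical linearizing transform
(e.g. inverse: y on 1/d; power: ln y on ln d; logistic, in its
no-upper-bound form 1/y = b₀·b₁^d: ln(1/y) on d). R², adjusted R² and
the overall-F p-value are reported in that fitting space. This is the
convention of SPSS-style curve estimation, and it is the only convention
under which growth, exponential and logistic — three parameterizations
of one regression of ln y on d — share an identical R², a tie the
package's tests pin down as an exact property. The cost is that R²
values of raw-space and log-space families are not strictly
commensurable; adjusted R² comparison across them is inherited from the
same convention.

Zero counts are a domain violation for log-response families and raise
an error listing the offending plots; an explicit `on_zero="drop"`
exclusion is available and reported. At projection time, distances below
ε = 1e-6 × median positive distance are floored before evaluating the
singular forms (inverse, logarithmic, power), so the centroid pixel
receives a finite, maximal prediction. Negative predictions are clamped
to zero only in map surfaces — never during fitting or validation — so
the regression statistics stay faithful to OLS. Because the inverse form
diverges as d → 0, pixels much closer to the centroid than any training
plot receive extrapolated densities that can exceed the observed range;
the uncertainty surfaces are the honest way to read those pixels.

Model selection maximizes adjusted R², breaking ties toward fewer
predictors and then a fixed family order, so selection is fully
deterministic.

## Validation and uncertainty

Split validation partitions the plots at random (training size =
round(0.70·n), at least p+2 records on each side; 15/7 at n = 22),
refits the chosen family on the training part, predicts the held-out
part, and regresses observed on predicted abundance; (r, r², p) per
trial plus mean/SD/min/max summaries are reported over 10 trials.
Degenerate trials (constant predictions) are flagged and excluded from
summaries.

The uncertainty procedure repeats a 65/35 split 1000 times (14/8 at
n = 22) — subsets drawn without replacement, not classical
with-replacement resampling — refitting on each training part and
predicting the full pixel grid. Per-pixel standard deviation and
2.5th/97.5th percentile bands across iterations form the uncertainty
map. Coverage is scored differently: each iteration's refit produces a
95% OLS *prediction interval* (in fitting space, back-transformed
monotonically for log-response families) for its held-out plots, and
coverage is the percentage of held-out observations falling inside.
Percentile bands of fitted-mean predictions capture estimation spread
but not observation noise, so they cannot attain nominal coverage of
noisy observations (on well-specified synthetic data they cover ~9%,
versus ~95% for prediction intervals); both are exposed
(`ci_method="prediction"` default, `"percentile"` optional). Held-out
zero counts cannot be scored in log space and are excluded from the
tally for log-response families; iterations whose refit hits a domain
violation are redrawn and counted. The family selected on the full data
is used in every trial and iteration — selection is not repeated per
split.

`percent_decline` reports both the exact percentage and its
nearest-integer rounding; it deliberately reports only computed values
(25 → 18 individuals is 28%, whatever a narrative rounds it to).

## The synthetic generator

`SyntheticConfig` draws P independent white-noise fields, smooths them
with a Gaussian kernel (σ = `autocorrelation_length` cells, default 5),
standardizes per layer and mixes through the Cholesky factor of
`true_covariance`, so the marginal pixel distribution has the requested
mean and covariance while staying spatially autocorrelated. The true
distance surface comes from the *generating* centroid/covariance, the
expected density from λ(d) = max(0, b₀ + b₁/max(d, ε)), occurrences are
drawn without replacement with probability ∝ exp(−decay·d) (decay 1.0
by default — a center-weighted cloud with one interpretable knob), and
plots are distinct uniform cells with Poisson (or rounded-Gaussian)
counts. Every artifact is bit-reproducible from (config, seed), with
per-role child seeds so sampling order is irrelevant.

Default parameters describe a survey-scale study system: 200×200 cells,
P = 4 layers, 241 occurrences, 22 plots, and an inverse law (b₀ = 1,
b₁ = 25, ε = 0.5) whose Poisson counts land in roughly the 1–25
burrows/km² range and whose full-data inverse fit averages adjusted
R² ≈ 0.70 at n = 22 — the statistical regime of the field survey the
package ships (`mapimi_burrow_counts()`). The landscape is multivariate
normal, so pixel distances concentrate near √P; real landscapes have
heavier distance tails, more extreme environments and survey bias, none
of which the generator emulates. Passing tests therefore demonstrate
correctness of the machinery and behaviour under the assumed
data-generating process, not performance on real rasters.

`recovery_benchmark_config()` is a deliberately high-abundance virtual
species (b₀ = 100, b₁ = 150, ε = 0.05, 200 plots). Poisson noise is
relative — CV = 1/√λ — so demanding 10% recovery of an intercept near 1
burrow/km² is statistically impossible at any realistic plot count; the
benchmark instead raises the density scale until both coefficients are
identifiable at n = 200, which a power check across 40 seeds confirms
with wide margin. The near-zero floor keeps the generating law exactly
inverse over the sampled distance range.

## Problem sizes in the shipped tests

Unit and property tests run on 5×5 to 20×20 grids with brute-force
oracles; statistical tests use 60×60 to 200×200 landscapes, 20
replicates for recovery and selection-majority checks, 10-replicate
averages for monotone-trend checks, and 1000 bootstrap iterations for
coverage — sizes chosen so each statistical claim has comfortable
Monte-Carlo margin while the whole suite runs in seconds.

## Known limitations

* No reprojection, resampling or GeoTIFF support: rasters must be
  co-registered ESRI ASCII grids in one CRS.
* The spatial-autoregressive alternative sometimes reported alongside
  these curve families is out of scope, as are count GLMs
  (Poisson/negative-binomial) and information-criterion selection.
* Coverage is scored at plot level; per-pixel coverage would require
  abundance observations at pixel scale that burrow surveys do not
  provide.
* Adjusted-R² selection among families fitted in different response
  spaces inherits the classical curve-estimation convention; it is a
  comparability compromise, not a likelihood-based comparison.
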