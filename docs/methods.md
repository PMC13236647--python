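# Methods

This note records the model, assumptions, numerical choices and known
limitations of the `greenmood` package.

## 1. Negative-emotion indicator

Posts carry a point location, a timestamp and a sentiment label in
{positive, neutral, negative}. Seasons are meteorological within a single
study year: Mar–May spring, Jun–Aug summer, Sep–Nov autumn, and winter =
Jan, Feb and Dec of the same year (a single-year window, not a
cross-year Dec–Feb window; the winter estimate therefore mixes the
year's two cold ends).

Negative posts per season enter a planar kernel density estimate

```
f(s) = Σᵢ (1 / (n h²)) · K((s − sᵢ) / h)
```

with the quartic kernel `K(u) = (3/π)(1 − ‖u‖²)²` on `‖u‖ ≤ 1` by
default (Gaussian and uniform are selectable). With this normalization an
interior surface integrates to 1, which is verified to ±1% by quadrature
in the tests; the density value at a single event's own location is 3/π
for unit bandwidth. Default bandwidth is 1000 m and cell size 150 m;
densities are evaluated at cell centers with an exact support window per
event.

The community indicator is the mean surface value over the cells whose
centers fall inside the community footprint, divided by population in
units of 10,000 residents. A footprint smaller than one grid cell covers
no cell center; the pipeline uses a nearest-cell centroid fallback
(elsewhere it is an error unless requested). Because the indicator is a
density per m² per 10,000 residents, its absolute scale is small; all
downstream analyses are scale-free (ranks, signs, R²) or internally
standardized.

## 2. Green-space covariates

Fourteen covariates per community: `ndvi`, `gvi`, `outdoor_access`,
`green_access`, `openness`, `walkability`, `lpi`, `pd`, `ed`, `shdi`,
`residential_density`, `female_share`, `night_light`,
`lockdown_intensity`.

- NDVI = (NIR − Red)/(NIR + Red); cells with zero band sum are missing
  and excluded from community means.
- Street-view scores use a two-level mean — per sampling point over
  viewing directions, then per community over points — which differs
  from the pooled mean when direction counts differ.
- Catchment counts use a closed boundary (a destination exactly at the
  threshold distance counts); the default walking threshold is 1000 m.
- Landscape metrics on class rasters follow the standard definitions:
  LPI = 100 · (largest patch area / landscape area); PD = patches per
  100 ha; ED = internal class-boundary length (m) per ha, with the
  landscape border and nodata boundaries excluded; SHDI = −Σ pᵢ ln pᵢ
  in nats. Patches are connected components with 8-neighbor
  connectivity by default. All four metrics are tested against an
  independent brute-force oracle on random small rasters.

## 3. Spatial autocorrelation

Weights are k-nearest-neighbor (k = 8) on planar centroid coordinates,
row-standardized; distance ties are broken by unit index so results do
not depend on input order. Global Moran's I uses a two-sided permutation
test around the null expectation E[I] = −1/(n−1). Local Moran's I uses
conditional permutation (the focal value held fixed, neighbors drawn
from the remaining values) and classifies significant units into
HH/LL/HL/LH by the signs of the standardized value and its spatial lag.
Under i.i.d. noise the non-null classification rate at α = 0.05 stays
below 10% (the conditional permutation test is conservative).

## 4. Models

All models act on a `ModelFrame` (covariates X, response y, planar
coordinates). The response in synthetic studies is either the latent
emotion (recovery tests) or the KDE indicator (pipeline runs).

- **Global random forest.** scikit-learn regressor, default 500 trees in
  the library API and 100 in the pipeline config, `min_samples_leaf` 3,
  single-threaded for reproducibility. The global fit passes explicit
  unit observation weights so that it is the exact global limit of the
  weighted local fits (observation weights enter the bootstrap draw, so
  a weightless fit would consume the random stream differently).
- **GWR.** Per-location weighted least squares over the location's
  adaptive neighborhood (its `bandwidth` nearest communities) with
  bisquare kernel weights `(1 − (d/dmax)²)²`; a rank-deficient local
  design falls back to a small ridge penalty (1e-6, warned).
- **GWRF.** One random forest per community, trained on its adaptive
  neighborhood with the kernel weights as observation weights. With
  bandwidth = n and the uniform kernel every local forest equals the
  global forest bit for bit under a shared seed — an exact oracle used
  in the tests. Prediction at a new point uses the nearest fitted
  location's forest (no blending, for auditability). Default adaptive
  bandwidth is 80 neighbors with a minimum local sample of 30;
  bandwidth can be selected by out-of-bag RMSE grid search.

**Evaluation.** R², MAE, RMSE; in-sample, out-of-bag, or spatially
blocked cross-validation (KMeans clusters of the coordinates as folds,
default 5). Spatially blocked CV forces extrapolation across space;
under strong spatial non-stationarity global models can score *negative*
held-out R² on the heterogeneous synthetic city. The meaningful
comparison is the ordering — GWRF above GWR and the global RF — which is
what the acceptance tests assert, alongside a linear negative control on
which GWRF shows no advantage over the correctly specified global fit.

## 5. Attribution

- **Shapley values.** The value function is interventional: v(S) is the
  model prediction with features in S from the explained observation and
  the rest replaced by background rows, averaged over the background.
  `exact_shapley` enumerates all 2^p coalitions (p ≤ 16) and satisfies
  efficiency, null-player and symmetry exactly; for a linear model it
  equals β·(x − x̄_background) to 1e-10. `sampled_shapley` is the
  permutation estimator with per-factor Monte-Carlo standard errors;
  efficiency holds exactly by telescoping. `shapley_matrix` batches many
  observations with shared permutations into a single model call.
- **Dominant factors.** Per community, φ is computed under the
  community's own local forest with its neighbor set as background, so
  attributions are relative to the local context. Both the background
  and the explained observations are subsampled following the local
  kernel weights, and the final mean |φ| is kernel-weighted — the
  attribution sees the same spatial weighting as the fit. The dominant
  factor is the argmax of the kernel-weighted mean |φ| over all 14
  factors (controls included); ties break by configured factor order.
- **Partial dependence.** Mean response over observations as one factor
  sweeps a quantile grid (default 20 points) of its observed values. The
  band is the across-observation standard deviation — a dispersion band,
  not a confidence interval. Thresholds are located at the grid argmin
  (valley) or argmax (peak).
- **Local effect surfaces.** Per community, the least-squares slope of
  the local forest's PDP over the neighborhood's factor range; locally
  constant factors are flagged and excluded.

## 6. Synthetic city generator

The generator is the package's ground-truth instrument, not a city
simulator. Communities are a Thomas-like clustered point process with
Voronoi footprints clipped to the extent; populations are lognormal.
Regions are contiguous vertical bands (nearest of region centers spread
along x). Each covariate is a smooth random cosine field plus
independent noise, mapped to a declared range; vegetation covariates and
lockdown intensity shift seasonally.

The latent negative emotion is

```
latent = base + Σ_f m_region(f, r) · m_season(f, s) · g_f(x_f) + ε,
ε ~ N(0, 0.02)
```

with g_f linear or piecewise-linear. The reference design encodes the
structure the pipeline must recover: the NDVI effect reverses sign at
NDVI = 0.5 (negative below, positive above), the green-access effect is
positive in region 0 and negative in region 1, and effects are strongest
in spring and mildest in winter. Effect magnitudes were calibrated once,
at design time, so that the two designated drivers dominate their
regions in the noise-free latent truth; they were not adjusted against
test outcomes. Posts per community are Poisson with rate proportional to
population; the probability that a post is negative is a logistic
function of the latent level (bounded by 0.6).

Reference conditions: 300 communities in a 30 × 30 km extent, two
regions, ~50 posts/community/season, noise SD 0.02.

## 7. Problem sizes and numerical choices

These are package choices made for desk-scale runtimes, not estimates of
any external study:

- Reference recovery runs: 300 communities, GWRF bandwidth 80, 100
  trees; dominant-factor attribution with background 16, 8 observations
  per community, 48 permutations. Recovery of the off-boundary
  (neighborhood ≥ 90% within one region) effect signs and dominant
  factors exceeds 85%, and the fitted NDVI turning point lands within
  one quantile-grid step of 0.5.
- Pipeline and example configs use 60–80 communities, 25–100 trees,
  and KDE cells of 100–150 m.
- Model comparison uses 60 trees under 5-fold spatially blocked CV.
- All derived seeds come from `numpy.random.SeedSequence` spawning and
  are reduced mod 2³¹; forests run single-threaded.

## 8. Limitations

- The KDE indicator inherits a footprint-area confound (post counts
  scale with population, density divides by area); its expected value is
  the negative-share over area, which the tests use as the recovery
  target.
- Spatially blocked CV is pessimistic under non-stationarity; absolute
  held-out R² values can be negative and should be read comparatively.
  In-sample and out-of-bag modes are also available.
- PDP bands are dispersion bands, not confidence intervals; threshold
  location is grid-resolution limited.
- The Shapley value function is interventional masking; tree-path
  conditional variants are out of scope, as are interaction values.
- GWRF predictions at new locations use the single nearest fitted
  forest; no distance blending or uncertainty is provided.
- The generator's smooth fields and Voronoi footprints are idealized;
  results on it validate the machinery, not any real city.
- All coordinates are planar meters; no CRS handling.
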