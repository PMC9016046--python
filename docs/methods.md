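# Methods

This note documents the models, conventions and design choices behind
`forestdyn`, in the spirit of a statistical-software methods appendix. It
describes what the code computes and why; every number quoted as a result is
produced by the test suite or `scripts/acceptance.py`, not asserted here.

## Data model

A dataset couples three tables: tree records (plot, census, species, dbh in
cm, optional age, expansion factor in stems ha⁻¹), plot descriptors
(planar metric coordinates, elevation, aspect class, protection zone, soil
texture/depth/type, the species set expected under potential natural
vegetation (PNV), per-period disturbance flags) and a species-trait table
(conifer flag; seral class in {early, late, rare, other}). Trees below the
6 cm caliper threshold are outside the sampled population and are rejected
at read time with a count. The expansion factor defaults to 20 (a 500 m²
plot) but is stored per record so concentric designs remain representable.
Rasters use the ESRI ASCII grid text format with cell-center semantics and
−9999 as the default nodata sentinel; coordinates are bare planar meters
(no CRS machinery — all distances in the analysis are metric).

## Indicators

Structure: basal area Σ wπ(d/200)², stand density Σ w, large-tree density
(strictly dbh > 50 cm), and the dbh standard deviation weighted by the
per-tree expansion factor. The *population* form of the weighted SD is used
(divide by Σ w, no n−1 correction): expansion factors are frequency weights
for which the population form is the natural limit, and with uniform weights
it reduces to the plain population SD. Composition: basal-area shares (%)
of conifers and of the three seral classes, and the Hill number of order 1
(exp of Shannon entropy of basal-area proportions). Conifer share and seral
shares classify independently: a coniferous species of seral class "other"
counts toward conifer share but toward no seral share, since the seral
classes need not partition the species pool. Empty plot-censuses yield all
zeros (including the Hill number, whose empty-set limit is taken as 0; any
non-empty plot has effective species number ≥ 1).

## Change statistics

Annual change is the indicator difference between two censuses divided by
the year difference. Standardization divides each indicator's per-plot
changes by the maximum *absolute* change across plots, preserving sign while
scaling the strongest change to magnitude 1 (an all-zero indicator is left
at zero rather than 0/0). Composite (hot-spot) change is the mean of a
group's standardized changes; structure = {basal area, density, large trees,
SD dbh}, composition = the five remaining indicators. Acceleration is the
landscape-mean annual change of the second period minus the first, reported
with SDs, alongside the difference of |mean| rates (direction-free
acceleration) and rates relative to the first-census landscape mean. Period
lengths come from the configured census years (12 and 15 y by default);
within-period visit dates are not modeled. The full-span rate is, by
construction, the day-weighted mean of the period rates (12/27, 15/27) —
asserted numerically in the tests. An elevation-stratified summary splits
standardized changes at a configurable threshold (1400 m by default, the
montane/subalpine transition); an empty stratum yields an undefined (NaN)
difference rather than a fabricated zero.

## Geostatistics

The Matheron estimator bins squared pairwise differences into 15 equal-width
lag bins up to a cutoff of one-third the maximum inter-point distance
(empty bins dropped). Five variogram families are fitted by weighted least
squares with weights N_j/h_j² (many close pairs dominate, as in common
geostatistical practice): Spherical, Exponential γ = c(1 − e^(−h/a)),
Gaussian γ = c(1 − e^(−(h/a)²)), Matérn in the Bessel-K form with
smoothness κ, and Stein's Matérn parameterization (distance rescaled by
2√κ, making the range roughly smoothness-invariant). κ is searched over
{0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1, 1.5, 2, 3, 5, 10}. Starting values:
nugget = first-bin semivariance, sill = mean of the last three bins,
range = half the cutoff; a second start from nugget 0 guards against the
first start's local minimum. Ties in weighted SSE break by the family order
listed above. Note the families overlap: Matérn κ = 0.5 *is* the
exponential model and any Matérn curve is exactly representable in Stein's
form, so the fitted family label is only identifiable for the Spherical and
Gaussian shapes; recovery checks therefore compare fitted curves, not
labels. The effective range reported alongside fitted models is the lag at
which the curve reaches 95% of its sill above the nugget.

Ordinary kriging solves the standard system (semivariance matrix bordered
with the unbiasedness constraint; weights sum to 1) with γ(0) = 0 on the
diagonal and in the right-hand side, making predictions at data locations
exact even with a nugget. For up to a few thousand points one global
factorization is reused for all grid cells; a k-nearest-neighbor local
variant exists for larger problems. Duplicate coordinates are averaged
(with a warning path) to keep the matrix nonsingular. Prediction grids use
100 m cells covering the plot bounding box padded by one cell. An all-zero
change field skips kriging and emits a zero raster, since its semivariogram
is undefined. Pattern comparison between period maps reports RMSE over
valid cells and trend congruence — the percentage of cells where the sign
of change persists (zero congruent only with zero).

## Driver attribution

Thirty covariates in four groups: legacy (8-class development stage, total
basal area, 90th-percentile tree age, PNV divergence — all valued at the
period's first census), disturbance (management zone, per-period disturbance
flag), climate (temperature / precipitation / radiation anomalies for the
four meteorological seasons and annually: period mean of daily values minus
the full-record mean, so day-weighted anomalies sum to zero), and site
(elevation, aspect, roughness, TRI, TPI, sand, clay, soil depth, soil
type). The terrain indices follow the standard 3×3-neighborhood
definitions (max−min range; mean |Δelevation| to the 8 neighbors; deviation
from the neighbor mean); border cells use the neighbors that exist, and
aspect is the steepest-descent compass direction discretized to 8 classes
with a separate "flat" class below a 10⁻⁶ slope. PNV divergence is
max(0, (0.5 − s)/0.5)·100 with s the basal-area share of the plot's PNV
dominants: meeting the conventional 50% dominance expectation scores 0,
total absence 100. The divergence normalization and the daily (rather than
summed) treatment of precipitation/radiation anomalies are the two places
where published usage is ambiguous; both choices are documented here and
isolated in single functions. Development stage uses a deliberately simple
stand-in classifier on quadratic-mean-dbh bands, stem density and the dbh
coefficient of variation (high variation in mature stands → plenter); it is
an approximation adequate for a categorical legacy covariate, not a
reimplementation of any published stage-classification decision tree.
Dominant age uses the nearest-rank weighted 90th percentile (no
interpolation ambiguity).

Each (indicator, period) response is modeled with gradient-boosted
regression trees (squared-error loss; scikit-learn backbone). Tenfold CV
folds are drawn once per response and reused along the whole elimination
path so RMSE differences reflect covariate sets only. The ensemble size is
chosen to minimize pooled held-out squared error over the staged
predictions; influence is split-improvement importance from a final
full-data fit at that size, with one-hot dummy importances summed back to
the parent covariate and normalized to 100%. Backward elimination drops the
single least-influential covariate per step (ties alphabetical) down to one
covariate; the candidate with minimal CV-RMSE wins, ties to the smaller
set. Aggregation across models weights each influence vector (zeros for
covariates eliminated from that model) by max(CV variance explained, 0) and
renormalizes to 100%; separate aggregates are produced for structural,
compositional and all responses. Moran's I of final-model CV residuals uses
row-standardized k = 8 nearest-neighbor weights with null expectation
−1/(n−1); at a few hundred observations one draw of the statistic has
sampling SD ≈ 0.03 even for white-noise residuals, so scene-level summaries
use the median across models rather than the extremes.

Default hyperparameters in `BRTConfig` follow conventional BRT practice
(learning rate 0.01, interaction depth 3, bag fraction 0.5, up to 5000
trees, tenfold CV). The pipeline and the acceptance script use the
`desk_scale` setting (learning rate 0.2, 45 trees) so that the 18-model
backward-elimination stage of a ~280-plot scene completes in a few minutes
on one CPU; with the coarser learning rate the selected ensembles sit well
inside the tree budget.

## Synthetic landscape

The generator is a fixture factory, not an ecological model: it reproduces
the statistical structure a repeated mountain-forest inventory exhibits —
spatial autocorrelation of terrain, soils and climate; elevation zonation;
demographic rates that respond to temperature anomalies and are damped by
standing basal area — with all imposed effects recorded in a
`SyntheticTruth` object. Terrain is a superposition of random Gaussian
bumps rescaled exactly to the configured elevation range (default
600–2100 m for the desk scene); soil fields add unit-variance
Gaussian-filtered noise (a Gaussian-family variogram with range 2σ, recorded
in the truth) to elevation trends. Plots sit on the 200 × 100 m grid nodes
below the 1700 m timberline (~280 plots on the default 3.6 × 1.8 km
extent; three censuses 1984/1996/2011 yield ~16,000 tree records). The
western quarter of the extent is the management zone, and random rectangles
covering ~5% of plots per period set the disturbance flags.

Daily climate per plot combines a seasonal sinusoid, a −0.0065 °C/m lapse
rate, white noise (SD 1.5 °C), and a warming step applied from 1996 onward
whose landscape mean is exactly 0.21 °C, varying smoothly between plots
(SD 0.5 °C) with independent per-season jitter (SD 0.35 °C, centered).
The per-plot deviations are what make the temperature-anomaly covariate
*identifiable* at desk scale: they are deliberately larger than the
between-plot climate spread of a real 100 m climate product, trading
realism for statistical power at ~300 plots (a real inventory has an order
of magnitude more plots and weaker per-plot noise). The per-season jitter
makes seasonal anomalies noisy copies of the annual anomaly, so the annual
anomaly — the quantity the demography actually responds to — is the
cleanest predictor rather than an arbitrary member of a collinear set.

The annual demographic loop (15 burn-in years before the first census, so
stands start near demographic equilibrium) applies: diameter growth
increasing with tree size, multiplied by exp(temp_effect · anomaly),
exp(−legacy_damping · BA/40) and a species-specific temperature modifier
(broadleaves favored, conifers and early-seral species penalized under
warming — the same modifier divides mortality); density- and
disturbance-driven mortality (a disturbed plot loses ~35% of stems in one
event year); and Poisson recruitment at 6–10 cm dbh, amplified by warmth,
damped by basal area, with the conifer share of recruits rising with
elevation and falling with warmth. Defaults: temp_effect 2.0,
legacy_damping 0.8, species-sensitivity scale 2.0. Under these conditions
the structural driver models reach CV R² ≈ 0.35 and the compositional ones
≈ 0.1, matching the magnitudes reported for real mountain-forest
inventories, and the imposed effects are recovered by the full pipeline
(majority-positive acceleration; annual-temperature anomaly top-3 for
compositional change; total basal area top-3 for structural change).

What passing these tests does *not* show: realism of absolute demographic
rates (they are free parameters recorded in `truth.json`), seed-dispersal
or bark-beetle dynamics, hydrological climate structure, disturbance
severity gradients, or behavior at the full ~3800-plot scale of a real
network.

## Numerical and degenerate-input conventions

Round-trip raster I/O is exact to 10 significant digits. Weighted
percentiles use nearest-rank (no interpolation). Kriging systems fall back
to least squares if a bordered matrix is singular after deduplication.
Standardization of an all-zero change field leaves zeros; composite change
of an empty group is an error; acceleration requires exactly three
censuses; Moran's I refuses constant residuals (undefined) and fewer than
10 observations. Negative CV variance explained is clipped to zero for
aggregation weights; if every weight is zero an unweighted mean is used and
flagged. All randomness flows through `numpy.random.default_rng` seeds;
fixed seeds give bit-identical tree tables and pipeline outputs.

## Known limitations

No edge correction for trees near plot boundaries (plot-level aggregates
treat the 500 m² plot as the population). No kriging variance maps,
anisotropy or co-kriging. The development-stage classifier is a documented
approximation. The backward-elimination path refits the full CV at every
set size, which dominates runtime; the desk-scale BRT setting trades some
smoothness of the CV-RMSE path for speed. Importance is split-improvement
only; marginal-effect (partial-dependence) importance is out of scope.
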