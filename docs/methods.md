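# Methods

## The estimation problem

An exponential resource selection function (RSF) states that the density
of an animal's use over available units is proportional to
`exp(β'x)`.  With used points (telemetry fixes) and available points
(uniform in the availability domain) stacked as a case/control sample,
the log-odds of "used" at covariates `x` is exactly `β'x + c`, where `c`
collects the used:available ratio and the availability normalising
constant.  Logistic regression of case status on the covariates is
therefore a correctly specified maximum-likelihood estimator of the
selection slopes — with one caveat that drives a key design choice below.

Covariates: binary canopy cover `CC`; monthly mean snow depth `SD` (cm);
feeding-site proximity `1/Dist_FS` (1/m), the reciprocal of the 3-D path
distance to the nearest supplemental feeding site; and the interaction
`SD/Dist_FS` (cm/m).  Proximity rather than distance is used because a
linear distance effect keeps acting far beyond any plausible perception
range; the reciprocal decays to ~0 within a few hundred metres.
Distances are floored at half a covariate cell (50 m at the default
100 m resolution) before inversion, since `1/Dist_FS` is unbounded at a
site itself and the appropriate scale at the site is the cell.

### Month-stratified intercepts

When one model pools several winter months, each month has a different
availability normalising constant: `Σ exp(β'x)` over the (identical)
available area is much larger in a snow-free November than in a deep
February.  A single pooled intercept then forces the slopes to absorb
month-level differences, which measurably biases the snow slope and the
interaction (2–4 standard errors at n ≈ 4000 in simulation).  `fit_rsf`
therefore supports a `strata` argument giving each month its own
intercept while slopes stay shared; the pipeline always fits with
`strata="month"`.  Intercepts are nuisance parameters: prediction uses
the slopes only, and the linear rescaling of the prediction surface
absorbs any constant anyway.  With stratification, simulated recovery
z-scores `(β̂ − β)/SE` are centred on zero with near-unit spread.

### Design construction

* One fix per animal per day is kept (uniformly at random, seeded) to
  break serial autocorrelation in high-rate GPS schedules.
* The population home range is the 99% isopleth of a product-Gaussian
  kernel density with the per-axis reference bandwidth
  `h = σ_axis · n^(−1/6)`, computed on the raster grid: cells are ranked
  by density and accumulated until 99% of the kernel mass is covered.
  The mask representation (rather than a vector contour) is exact for
  every downstream use, all of which are cell-membership tests.
* Available points are sampled 1:1 with used points, uniformly over the
  polygon's cells, and inherit the month of their paired used point so
  both rows of a pair read the same monthly snow layer.
* The ~1% of used fixes falling outside the 99% polygon are dropped:
  the likelihood contrasts use against availability *within* the home
  range, and keeping fixes in cells the availability sample cannot reach
  attenuates every slope (measured 1–4 SE at default sizes).
* Covariates are standardized internally before optimisation (proximity
  is ~10⁻³ while its slope is ~10²) and slopes/SEs are mapped back
  exactly; Newton iteration with an L-BFGS fallback, gradient tolerance
  1e-8, 100 iterations.

## Prediction and map comparison

`Rp = LinScale(exp(β̂'x))` is computed cell-wise without intercept; the
surface is shifted by its maximum before exponentiation for overflow
safety (LinScale is invariant to constant shifts of the linear
predictor).  A constant surface sets a degenerate flag and returns
zeros.

All monthly Rp maps are binned into 10 quantile classes whose edges are
pooled from the contemporary model's predictions across the whole study,
with ±∞ sentinels and right-closed intervals (a value equal to an
interior edge falls in the lower bin).  One shared pooled scale keeps
bins comparable across periods and scenarios.  Pairs of binned maps are
compared at 1000 random points, drawn once per batch inside the
intersection of the two periods' 99% polygons and reused for every pair,
with Cohen's kappa under linear disagreement weights
`v_ij = |i−j|/(n_bins−1)`:

    κ = 1 − Σ v·observed / Σ v·expected

(1 for identical maps, ≈0 at chance agreement).  Linear rather than
quadratic weights implement "penalty proportional to rank distance";
the choice is exposed in the implementation if quadratic behaviour is
wanted.  Five comparison categories are recorded (year-to-year within
the historical and contemporary periods, between decades, and within the
intermediate and severe forecast scenarios); per month, a one-way ANOVA
with post-hoc Tukey HSD tests for category differences.  November is
excluded from the ANOVA by default (few records, near-constant maps).
Subtraction maps difference the bin indices (later − earlier), bounded
by ±9 for ten bins.

## Validation

* **ROC AUC** of the fitted scores against case labels (rank
  formulation; ties count half).
* **Area-adjusted-frequency τ**: an Rp surface is cut into `n_bins`
  quantile classes by cell count; each bin's adjusted frequency is
  (share of used points) / (share of area); Kendall's τ between bin rank
  and adjusted frequency measures calibration.  Kendall's τ-b is used
  (tie-corrected; exact p for small tie-free samples, normal
  approximation otherwise).  Monthly validations with fewer than 10 used
  points are refused rather than reported.
* **5-fold cross-validation**, stratified by case so every training set
  keeps the 1:1 balance: each fold is held out, the model refit on the
  rest, held-out used points binned on the refit model's per-month Rp
  surfaces (quantile classes by cell count are area-balanced, so bins
  pool cleanly across months), and the fold's τ computed.  When no
  rasters are supplied, binning falls back to score space with the
  held-out available rows as the areal sample; the two agree as the
  available sample grows because the score is a monotone transform of
  Rp and available points are uniform in area.  Spatial and temporal
  validation are the same computation with different inputs.

## The synthetic study system

The generator emulates the statistical structure the analysis assumes,
with the truth in hand so estimation error is measurable.

* **Terrain**: a valley-to-ridge ramp (400–3500 m) with smooth seeded
  noise (default 110×110 cells at 100 m); canopy as correlated forest
  patches below a 1900 m treeline.
* **Snow**: daily depth
  `max(0, lapse·(elev − snowline_month − shift) + offset_month + a_wm + ε)·scale`
  with lapse 0.06 cm/m, month-specific snowlines (lowest, 1000–1150 m,
  in January–March; 1300 m in April; 2000 m in November), interannual
  anomalies `a_wm`, and small daily noise (2 cm).  The interannual
  anomaly acts like a snowline displacement (±25 cm ≈ ±400 m), which is
  what makes year-to-year maps differ.
* **Winter severity structure**: each period's three winters carry fixed
  severities of −1, +1, 0 interannual SDs (a dry, a snowy, and an
  average winter, the contrast the subtraction maps need) plus residual
  month-level noise at 0.4 SD.  Fully i.i.d. anomalies would let all
  three winters of a period fall snow-free at the elevations the animals
  use, erasing the within-period variability the comparison stage
  studies.
* **Two periods**: historical — 20 feeding sites, high interannual snow
  SD in every month (35 cm in Dec/Apr, 25 cm otherwise); contemporary —
  95 sites, interannual SD suppressed to 4 cm in Dec/Jan/Apr, and mean
  depth offsets of −15 cm (Dec/Jan/Apr) / −10 cm (others) implementing
  the decadal snow decline.  Ground-truth coefficients differ between
  periods — historical (1.4, −0.05, 450, 5), contemporary (0.8, −0.05,
  300, 5) — a static structural contrast that lowers inter-decadal map
  agreement the way a behavioural shift between decades does, without
  suppressing historical year-to-year variability.
* **Scenarios**: the contemporary winters re-generated with the snowline
  shifted up 350 m (intermediate) or 700 m (severe) and the pack scaled
  by 0.9 / 0.8, sharing the contemporary anomaly draws so a scenario is
  "the same winters under a warmer climate".
* **Telemetry**: one cell per animal-day drawn with probability
  ∝ exp(truth linear predictor) over the whole landscape (the range
  limit emerges from snow avoidance, not a fence), the fix uniform
  within the cell; 8 animals × 28 days × 6 months × 3 winters ≈ 4000
  used points per period, matching the scale of realistic VHF/GPS
  studies; a fixes-per-day option exercises the daily subsampling.
  Draws are independent across days — the analysis thins to one fix per
  day precisely to break autocorrelation, so a point process is the
  appropriate generative model; no movement autocorrelation, diel
  structure, or individual heterogeneity is simulated, so passing tests
  demonstrate correctness of the estimation machinery, not robustness
  to those real-data features.

## Numerical conventions

* Planar metre coordinates; `values[row, col]` with row 0 at the south
  edge; cell centres at `origin + (index + 0.5)·cell_size`; alignment
  (origin, cell size, shape) is enforced for every cross-raster
  operation.
* Percentiles and quantile edges use linear interpolation between order
  statistics.
* Path distance uses 8-connected Dijkstra with step cost
  `sqrt(planar² + Δelev²)`; the 8-connectivity overestimates true
  geodesics by at most ~8.3% on flat terrain (documented bound).
* Every stage seed is derived as `hash(master_seed, stage_name)` (below
  2³¹), making runs byte-reproducible; reruns of the same configuration
  produce identical artifact hashes.
* Degenerate inputs error loudly: identical points for a kernel, empty
  site lists, constant maps at binning, all-tied vectors for τ,
  single-class designs, perfect separation.

## Known limitations

* The interannual snow anomaly is spatially constant within a
  winter-month; real anomalies have spatial texture beyond an elevation
  shift.
* Recovery z-scores through the full design path have slightly inflated
  spread (SD ≈ 1.1) because the home-range polygon is estimated from the
  same points it conditions; at the default sizes roughly one seed in
  twenty puts one slope marginally outside 3 SE.
* The k-fold score-space fallback and the raster-surface path agree
  asymptotically but not exactly at small n.
* Weighted kappa is computed at sampled points, not over all cells, so
  kappa records carry Monte Carlo noise of order 0.01 at 1000 points.
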