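# Methods

## The statistical model

The quantity modeled is the temporally adjusted annual average of an
oxidative-potential metric at monitoring site *i*:

    y_i = b0 + Σ_j b_j x_ij + e_i

fit by ordinary least squares over N ≈ 40 sites, where the x_j are
GIS-style predictors (buffer road length, traffic load, population,
seminatural/forested area) plus an interpolated regional background
estimate.  The model is *supervised*: every candidate predictor carries an
a-priori direction of effect (traffic and urbanity variables `+`,
seminatural/forested area `−`, regional background `+`), and a candidate
may only enter — and a fitted model only stand — while every coefficient
keeps its declared sign.

### Preprocessing

Each raw 2-week value is blank-corrected (subtraction of the assay's mean
field-blank: 0.12 nmol DTT/m³ for OP^DTT, 850 A.U./m³ for OP^ESR by
default) and adjusted by the contemporaneous deviation of a continuously
monitored reference site from its annual mean:

    adjusted = value − (ref_period − ref_annual_mean)

The correction is a *signed* additive shift.  A literal absolute value
would only ever lower values and would not center the series at the annual
mean, so "difference in absolute units" (as opposed to a relative/ratio
correction) is the implemented reading; no multiplicative variant is
provided.  Negative and below-LOD values are retained throughout.  By
default `ref_annual_mean` is the mean of the supplied reference periods;
it can be passed explicitly (e.g. the full-year mean of a continuous
series), in which case the adjustment is exactly invariant to a constant
shift applied to one period at all sites and the reference alike.  With
the mean recomputed from the shifted periods that invariance holds only
approximately (a shift δ in one of P periods moves annual averages by
δ/P) — the two conventions cannot both hold exactly.

### Selection protocol

1. **Zero-inflation screen**: drop predictors with exact zeros at strictly
   more than ⌈0.75·N⌉ sites (30 at N = 40).
2. **Forward selection**: at each step fit every remaining candidate
   alongside the current terms; eligible candidates are those whose trial
   fit keeps *all* signs conforming (not only the entrant's — sign-flipping
   models are rejected outright).  The eligible candidate with the highest
   adjusted R² enters if its gain exceeds 0.01.  Ties at machine precision
   go to the larger |t| of the entrant, then the lexicographically smaller
   name, so runs are deterministic.
3. **p-value pruning**: iteratively remove the worst term with p > 0.10
   (direction violations after refit are removed the same way).  If
   pruning removed anything, selection is *rerun* with the pruned terms
   blacklisted, iterated to a fixed point.  Rationale: a spurious early
   entrant can block a genuine candidate through the sign-conformity check;
   once the entrant is pruned, the blocked candidate deserves
   reconsideration.  Without this redevelopment step the protocol fails to
   recover known generating structures even on noiseless data.
4. **VIF pruning**: while any variance inflation factor exceeds 3, remove
   the worst offender, blacklist it, and redevelop (selection + p-pruning)
   on the remaining pool.
5. **Diagnostics**: per-site Cook's distance (max > 1 flags the model for
   examination; nothing is removed automatically) and Moran's I of the
   residuals under row-standardized inverse-distance-squared weights
   (binary k-nearest-neighbour weights are available), with expectation
   −1/(n−1), randomization variance, and a two-sided normal p-value.

Reported model tables follow the standardized convention: raw slope
multiplied by the predictor's P90 − P10 difference over the training sites
(linear-interpolation quantiles), standard errors scaled identically, the
intercept unscaled.  The "cumulative adjusted R²" column is the adjusted R²
of the model at the step each term entered.

### Validation

- **LOOCV** re-estimates the coefficients of the *fixed* final predictor
  set on N−1 sites and predicts the held-out site.  The primary R² is the
  squared Pearson correlation between observed and predicted (the
  convention in this literature); 1 − SSE/SST is reported alongside.  Note
  a degeneracy: for an intercept-only structure the leave-one-out mean is
  perfectly anti-correlated with the held-out value, so the Pearson form is
  1 while the variance-explained form is ≈ 0 — null-behaviour statements
  use the latter.
- **Holdout validation** draws `n_splits` (default 10) stratified 50/50
  train/test partitions (exactly half of each site type; fractional
  remainders are allocated to training at random) and reruns the *entire*
  development pipeline on each 20-site training half.  Reported as
  mean ± SE over splits, SE = SD/√n_splits.  Split k is seeded by
  `SeedSequence([seed, k])`, so adding splits never changes earlier ones.
  An empty refit model predicts the training mean; its test R² is recorded
  as 0.

The holdout R² sits systematically below the model R² (overfitting gap):
redeveloped 20-site models are less stable than the 40-site model, and the
gap widens with model size.  This is asserted as a ≥ 0 mean gap over 30
campaigns in the acceptance suite.

## The synthetic campaign generator

The generator emulates the study design: 10 regional-background, 12
urban-background and 18 street sites over a 200 km × 200 km planar region,
three 2-week periods per site (120 records per metric), one central
reference site, and two metrics with their own units, blanks and seasonal
offsets.

**Geometry.** 5–7 well-separated city centers; urban and street sites
scatter within ~3.5 km of their city; regional sites sit in small towns on
rings 8–36 km around the cities.  The ring layout matters: it makes each
city's interpolated background dominated by its nearby donors.  Were the
regional sites spread uniformly, the d⁻² weights at any city would be
near-uniform, the interpolated field would collapse toward the global mean,
and the regional term could never clear the 0.01 entry gain.

**Predictors.** Road length (500 m and a noisy 100 m companion), traffic
intensity × inverse distance to the nearest major road, traffic load in
50 m, population within 5 km, seminatural/forested area in 1 km, and an
industrial-area variable that is zero at ~85% of sites (so the
zero-inflation screen always has something to do).  Distributions are
site-type-dependent log-normals (skewed, partially zero-inflated at
background sites) and beta-distributed land-use shares; population carries
a smooth low-order polynomial trend.  Each "province" (a city's
surroundings) draws its own rural seminatural share, shared by the regional
sites in its ring — this between-province heterogeneity is what gives the
regional background field its spatial contrast.

**Truth.** The noiseless annual truth is *exactly* linear in the candidate
predictors as the pipeline computes them:

    y_i = a + b·g_i + Σ_j β_j x_ij

where g is the leave-self-out inverse-distance-squared interpolation of
the regional sites' truths.  Because g depends on those truths, the ten
regional values solve the fixed-point system
y_R = (I − bW)⁻¹(a + X_R β), with W the row-stochastic IDW weight matrix
among regional sites.  The term b·g then *is* the large-scale regional
trend.  This construction was chosen over adding an exogenous smooth
surface to the truth precisely so that zero-noise campaigns admit exact
recovery: an IDW interpolation of an arbitrary surface is not exact, and
any truth term outside the candidate span leaves residuals that bias every
slope.

**Default generating models** mirror the structure "regional background +
one local traffic variable + one urbanity variable": for OP^DTT
road length 500 m (+) and seminatural 1 km (−) with background weight
0.84; for OP^ESR traffic load 50 m (+) and seminatural 1 km (−) with
background weight 0.86.  Intercepts and slopes are set so annual averages
stay positive with wide margin, street means exceed urban means, and
RB/UB ≈ 0.85, S/UB ≈ 1.1 — the qualitative ordering expected of these
metrics.  Keeping to three terms is deliberate: every generating term must
contribute > 1% unique adjusted-R² gain for the protocol to admit it, and
with more terms that budget fails on a material fraction of random
geometries even at zero noise.

**Noise.** Measurement noise is Gaussian per 2-week sample
(0.84 nmol DTT/min/m³, 1600 A.U./m³ by default), applied to sites and
reference alike, calibrated so that OLS of the adjusted annual averages on
the true predictor set explains ≈ 70–75% of the between-site variance —
i.e. the generating model occupies the realistic middle ground between
deterministic and unlearnable.  Seasonal offsets are zero-mean by default
so the adjusted annual average is an unbiased estimate of the truth.
Seeding uses `SeedSequence(seed).spawn()` split into geometry, predictor
and noise streams; passing an explicit `geometry_seed` reuses one site
layout across noise realizations.

**What the generator does and does not emulate.** It reproduces the
design's site typology, the skew/zero-inflation of buffer variables, a
spatially structured regional background, seasonal offsets, assay blanks
and measurement noise.  It does not emulate real GIS geometry (predictors
are drawn, not computed from maps), correlated multi-pollutant panels
(NO₂, elemental composition), non-Gaussian assay error, missing periods,
or spatially correlated *residual* processes beyond the background term.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generating assumptions — not that LUR models of
real OP data will reach any particular R².

### Measured behaviour at the defaults

Quantities the test suite itself computes, at the frozen defaults:

- Noiseless campaigns: the full generating structure (both local terms and
  the regional background term) is recovered with slopes at 1e-8 precision
  on ≈ 99% of random seeds.  The residual ~1% are geometries where some
  term's unique adjusted-R² gain falls below the protocol's 0.01 entry
  threshold by chance; under that rule universal exact recovery is not
  attainable.
- Default-noise campaigns (50 seeds): the local generating predictors (or
  an |r| > 0.9 surrogate) are recovered in ≈ 95% (OP^DTT) and ≈ 85%
  (OP^ESR) of seeds, and the regional background term is included in
  ≈ 80–90%.  The limiting factor for the regional term is
  errors-in-variables attenuation: the interpolated estimate is built from
  noisy donor annual averages, which shrinks its fitted coefficient and
  occasionally pushes it over the p/gain thresholds.  "Recovery" in the
  acceptance suite is therefore asserted separately for the local
  generating predictors and for regional-term inclusion.

## Numerical choices and edge cases

- OLS via statsmodels; no regularization anywhere (out of scope by
  design).
- Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1); intercept-only models
  score 0.
- IDW with a coincident donor returns that donor's value (mean over ties):
  the exact-interpolation limit.  No search-radius cutoff; all regional
  donors contribute.  Distances are Euclidean on planar meters.
- VIF of a single-term model is 1; perfect collinearity reports +inf.
- Cook's D on a numerically perfect fit (SSR ≤ 1e-12·SST) is defined as 0;
  leverage-1 observations report +inf.
- Moran's I requires ≥ 5 sites and non-constant residuals; coincident
  points receive the row's maximum finite weight.
- `range_percent` refuses non-positive means; the log-ratio site-type
  analysis refuses non-positive values, and the report layer excludes such
  values from that step only (with a logged warning) — at default noise
  this affects roughly one site in two thousand.
- CSV dialect: UTF-8, comma-separated, header row, `.` decimals; period
  ids are opaque strings; coordinates planar meters; no CRS handling.

## Known limitations

- The supervised protocol is greedy; it is faithful to standard practice,
  not an oracle for the best sign-constrained subset.
- Holdout validation redevelops models on 20 sites, where the zero-screen
  threshold ⌈0.75·N⌉ = 15 generalizes the 40-site rule.
- The comparison stage synthesizes receptor predictor rows; comparisons
  against previously published models of other pollutants require the user
  to supply those models' serialized coefficients and matching predictors.
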