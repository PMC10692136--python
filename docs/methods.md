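# Methods

This note documents the models, estimators and numerical choices behind
`lakeews`, in the order data flows through the pipeline.

## Synthetic lakes

The generator exists because the analyses here need *labelled* transitions:
every classification and warning rule is scored against mechanisms that are
true by construction.

**Latent dynamics.** Each lake × trophic level carries one latent biomass
trajectory on a monthly grid, integrated by Euler–Maruyama with step
dt = 1/120 year (10 sub-steps per month) and multiplicative noise
`σ·X·dW` (default σ = 0.05 yr^(−1/2)), clipped at a tiny positive floor so
densities stay nonnegative. Six mechanisms are implemented:

- *Fold bifurcation* — the grazing-type consumer model
  `dX/dt = r·X(1−X/K) − c·X²/(X²+h²)` with r = 1, K = 10, h = 1. Numerical
  continuation of the equilibria places the folds at c ≈ 1.787 and
  c ≈ 2.604. The default control path approaches the fold slowly
  (c: 2.0 → 2.5 over half the series, letting critical slowing down
  develop), then ramps quickly to 4.5 so the collapse completes within about
  two years, and finally relaxes to c = 2.2 — inside the bistable band — so
  the state remains on the low branch and hysteresis is present by
  construction. A slow ramp straight through the fold was rejected: the
  saddle-node ghost stretches the collapse over ~5 yearly observations,
  which a six-knot smooth fits as well as a threshold model does, and the
  time-series and state-space breakpoints then disagree by more than the
  coherence tolerance. The fast-overshoot path is also the ecologically
  interesting regime: an abrupt observed collapse.
- *Step change* — fast Ornstein–Uhlenbeck tracking (θ = 12 yr⁻¹) of an
  equilibrium that jumps discontinuously at mid-series.
- *Noise-induced* — a cubic double-well drift with equilibria at 2, 5, 8 and
  large noise (σ = 0.6) under a constant driver; the shift time is the first
  sustained crossing of the unstable point.
- *Threshold-like* — fast tracking of a steep sigmoid response to a linear
  driver ramp; the state–driver map is single-valued, so no hysteresis.
- *Smooth trend* — fast tracking of a linear equilibrium drift.
- *Stationary* — an OU process (θ = 4 yr⁻¹) around a fixed mean.

**Drivers.** Total phosphorus is the forcing driver (a linear rescaling of
the control parameter into μg/L); nitrate and temperature co-trend weakly
with it, as monitored eutrophication drivers do, so the leading principal
component of the standardized drivers tracks the forcing. Temperature
carries an 8 °C annual sinusoid. Driver noise scales with the mechanism's σ
and is kept modest so yearly driver means are smooth — yearly abiotic
averages in monitoring data are far less volatile than plankton counts.

**Observation model.** The latent state receives a multiplicative seasonal
sinusoid (relative amplitude 0.3, monthly product only — it cancels to first
order in yearly means), is split into genus series by Dirichlet base shares
with AR(1) log-share fluctuations (shares renormalized each month, so genus
columns sum to the latent state exactly), and is observed through unit-mean
lognormal noise (CV 0.2) with a detection limit of 10⁻³ of the long-run mean
below which a zero is recorded. Default community sizes are 8 phytoplankton
and 4 zooplankton genera.

**What the generator does not emulate:** food-web coupling between trophic
levels beyond shared forcing, taxonomic misclassification, irregular or
missing sampling, and observer changes. Passing tests therefore demonstrate
that the pipeline recovers the constructed mechanisms under idealised
sampling, not that it would do so in any particular real lake.

## Standardisation

Unnamed or unidentified taxa are dropped; a taxon missing from a sampling
date on which the lake was sampled is recorded as density zero (constant
search effort implies below-detection). Densities are averaged to calendar
month and calendar year; species are averaged within the period first and
then summed into genera. On the monthly matrix, a genus is dropped when it
has any all-zero run strictly longer than 12 consecutive months ("longer
than 12 months" is read strictly: a 12-month absence is retained), and the
surviving genus set is applied to the yearly matrix. Periods with no
sampling stay as explicit missing values.

## Classification

**Penalized smooths.** Smooths are rank-reduced 1-D thin-plate regression
splines: the radial basis |x−x_i|³ on the distinct covariate values,
truncated to the leading k eigenvectors of the radial matrix with the {1, x}
null space constraint absorbed (basis dimension k ≤ 6 for the continuous
smooth, ≤ 3 per threshold segment). The smoothing parameter is chosen by
Gaussian REML (profiled scale; golden-section search over log λ ∈ [−12, 18]);
the effective degrees of freedom reported for the smooth exclude the
intercept, and GCV uses the full model dof, `GCV = n·RSS/(n−edf_model)²`.
During development the smoother was calibrated against an independent
reference GAM implementation on identical fixtures; the fitted edf agree to
≈0.05 on average and the noise-free cubic example reproduces the reference
exactly (relative MSE 8.4 × 10⁻⁴ — the eigen-truncation does not contain
cubics exactly, so this is the correct value for this basis, not a defect).

**Threshold search.** A threshold model is attempted only when the
continuous smooth's edf reaches 3 (an approximately cubic shape that can
contain a step). Candidate breakpoints are the midpoints between adjacent
sorted values of the *threshold variable* with at least 4 observations per
side; each side gets its own ≤3-knot smooth, and the minimum-GCV candidate
wins, with ties going to the earlier breakpoint and exact GAM/TGAM ties to
the continuous model. The threshold variable is time in both the
time-series model and the state-space model — in the state space a split
sorted by PC1 would make hysteresis overlap impossible by construction,
whereas a split in time lets the pre- and post-shift segments span
overlapping driver ranges. Because the edf gate measures "does this series
plausibly contain a step", the state-space threshold search is gated on the
*time* smooth's edf; a hysteresis loop is not a smooth function of the
driver, so the state-space continuous smooth's own edf would wrongly veto
it.

**State space.** Drivers are z-scored per column (constant columns dropped
with a warning) and the first principal component taken as the stressor
axis, sign-fixed so the phosphorus loading is nonnegative.

**Bimodality.** The sample bimodality coefficient uses bias-corrected
skewness g₁ and excess kurtosis g₂ (SAS convention):
`BC = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3)))`, with BC > 0.5 read as bimodal
(uniform ≈ 5/9, Gaussian ≈ 1/3).

**Hysteresis.** A state-space threshold fit is hysteretic when the two
segments' PC1 ranges overlap on an interval covering ≥10% of the combined
range, the overlap contains at least two observations from each segment, and
at some point on it the segments' pointwise 95% confidence bands are
disjoint. The two data-support clauses exist because a single-valued
threshold response with a noisy driver produces a noise-width, data-poor
overlap at the segment boundary; requiring substantive overlap separates
genuine dual states (driver relaxation after a fold) from that artifact.

**Fate decision.** Critical transition = time breakpoint + state-space
breakpoint within 2 years of it (configurable) + BC > 0.5 + hysteresis.
A time breakpoint without the full set is an abrupt non-bifurcation
(annotated "unimodal" when BC ≤ 0.5); no breakpoint with edf ≥ 3 is a
nonlinear-continuous change; anything else is no shift. The transition year
is the first year of the post-break regime. A known ambiguity, shared with
any observational classification: a noise-induced shift in a genuinely
bistable landscape can satisfy bimodality and overlap and be labelled
critical — distinguishing it requires knowledge of the governing equations,
which is out of scope.

**Trimming.** For downstream EWS assessment, any lake with a transition is
truncated strictly before its earliest transition year across both trophic
levels; lakes without transitions keep their first 85%. Trimmed series
shorter than 10 points are flagged, not dropped.

## Preprocessing

Detrending: none, linear (OLS residuals on the time index), LOESS (local
linear, span 0.5), or Gaussian kernel smoothing (Silverman bandwidth on the
time index by default). Deseasoning (monthly series only): none, calendar
month-mean subtraction, classical additive decomposition, or STL with a
periodic seasonal window; internal gaps are linearly interpolated for the
decomposition fits only. Order is detrend-first by default (switchable).
The factorial grid is 4 × 4 = 16 monthly combinations and 4 yearly ones.
The unit-range scaler maps a non-constant series to
`s = 1 + (x − x_min)/(x_max − x_min) ∈ [1, 2]`.

## Indicators and assessment

Univariate: ar1 (lag-1 Pearson), SD (n−1), skewness (bias-corrected g₁);
zero-variance windows propagate as missing. Composites (ar1+SD, ar1+skew,
SD+skew, ar1+SD+skew) sum the members' standardized expanding-window values
and exist only for expanding windows. Multivariate: per-column summaries
(meanAR, maxAR, meanSD, maxSD), covariance spectrum (eigenCOV = dominant
eigenvalue, maxCOV = largest off-diagonal), PC1-score series statistics
(pcaAR, pcaSD, plus pcaVE, the variance-explained alternative reading),
maximum-autocorrelation factors (Σ_Δ w = λ Σ w; eigenMAF is the smallest
generalized eigenvalue, mafAR/mafSD the first factor's score statistics;
singular covariance triggers one ridge-regularized retry with a warning),
and mutINFO — mean pairwise histogram mutual information with ⌈T^(1/3)⌉
equal-width bins per axis and Miller–Madow bias correction floored at zero,
so independent series score ≈ 0. Covariance-based indicators require
T ≥ p + 2 rows; community assessments skip an indicator (with a warning)
when a window cannot satisfy that.

Rolling windows use round-half-up(0.5·T) points; the trend statistic is
tie-corrected Kendall τ-b of indicator against window index, and the warning
requires τ > 0 and τ at or above the 95th percentile of 1000 taus from
time-permuted surrogates (the same permutation applied across genus columns,
preserving cross-sectional structure). Expanding windows compute the
indicator on all data up to t, standardise by the running mean and SD of the
raw indicator sequence (ddof 1), report standardized values only after a 50%
burn-in, and warn when > 2σ is exceeded at two or more time points
(cumulative by default; a consecutive variant is available). One-sided
exceedance follows the rising-indicator logic of CSD.

## Evaluation

Warnings are successes when they match the fate (warning on critical,
no warning on non-critical). Successes are aggregated per
(lake, fate, factor level) — univariate methods contribute one trial per
genus series, multivariate one per trophic level — and modelled as
`y ~ Binomial(n, π)`, `logit(π) = β_level + u_lake + u_fate + u_lake:fate`
with no global intercept, β ~ Normal(0, 1.2) truncated to (−5.5, 5.5)
(≈1%–99% probability), mean-zero random intercepts with Exponential(1)
scales. The residual term sometimes written in this model family has no
meaning under a binomial likelihood and is implemented only as an optional
observation-level intercept, off by default; with a single fate in the data
(separate true-positive/true-negative analyses) the fate terms drop out.

The posterior is sampled by Hamiltonian Monte Carlo with analytic gradients
under a non-centered parameterisation: 4 chains, leapfrog count jittered
uniformly in 8–24, dual-averaging step-size adaptation (target acceptance
0.8) in two warmup windows with a diagonal mass matrix estimated from mean
within-chain variances, the adapted step size shared across chains at its
median, and a per-iteration downward step-size jitter (×[1/3, 1]) so regions
stiffer than the adapted scale remain reachable. β truncation is enforced by
rejection; the bound sits 4.6 prior SDs out, so the truncated prior is
numerically a Normal(0, 1.2). Convergence is checked by split-Rhat on the
β draws (tolerance 1.05) with one automatic restart at doubled warmup before
raising. Defaults are 10,000 post-warmup draws per chain after 2,000 warmup
iterations; the test suite and acceptance script use 1,000–1,500 draws after
600–1,000 warmup, which split-Rhat shows is ample for this posterior
(≤ 35 dimensions). Summaries are inverse-logit medians with 50/80/95%
equal-tailed credible intervals; "better than chance" means the 95% interval
lies entirely above 0.5. Preprocessing selection fits the same model with
the 16 detrend × deseason combinations as the factor on critically
transitioning series only and reports the highest posterior median per
method class (alphabetical on ties, with a warning).

## Problem sizes and determinism

The shipped checks run the study conditions at: 100 step-change and 100
stationary series for breakpoint recovery/false positives; 50 lakes per
mechanism for classification rates; 100 stationary replicates at 1,000
permutations for warning calibration; 20 simulated trial tables (9 lakes ×
2 fates × 3 levels × 50 trials) for posterior recovery; 4,000 draws for the
prior-predictive comparison. All randomness flows through explicit integer
seeds (numpy Generator); repeated runs of the seeded pipeline are
byte-identical, including written CSVs.

## Known limitations

- The mechanism taxonomy is observational: cusp bifurcations and
  threshold-like responses, or noise-induced shifts in bistable systems,
  cannot always be separated without the governing equations.
- The hysteresis test needs the driver to relax into the bistable band; a
  fold crossed without relaxation is indistinguishable from a threshold
  response here, and is classified as an abrupt non-bifurcation.
- Indicator values on short yearly windows with many genera are limited by
  T ≥ p + 2 for covariance-based statistics.
- The indicator registry covers 19 indicators (3 univariate, 4 composites,
  12 multivariate, plus the pcaVE variant); spectral/reddening indicators,
  Fisher information and variogram methods are deliberately absent. The
  registry is string-keyed and extensible, so additional indicators can be
  scored without touching the assessment engines.
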