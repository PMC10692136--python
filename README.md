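# lakeews

Regime-shift classification and early-warning-signal (EWS) assessment for
multi-trophic lake plankton time series.

Long-term plankton monitoring series often show abrupt changes, but only a
subset of those are *critical transitions* — shifts across a fold
(saddle-node) bifurcation, which imply alternative stable states, hysteresis,
and in principle detectability through critical slowing down (CSD). Treating
every regime shift as a critical transition inflates the apparent skill of
generic early-warning indicators. This package implements the full analysis
chain needed to make, and then to score, that distinction:

1. **Mechanism pre-classification.** Yearly total plankton density per
   trophic level is fit with a penalized thin-plate smooth (GAM) and a
   *threshold* GAM (TGAM) — two ≤3-knot smooths joined at a breakpoint placed
   between adjacent time points and chosen by minimising
   `GCV = n·RSS/(n−edf)²`. The same comparison is run in the environmental
   "state space" (density against PC1 of temperature, nitrate and total
   phosphorus). A critical transition requires a breakpoint in time, a
   coherent breakpoint in state space, a bimodality coefficient
   `BC = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3))) > 0.5`, and hysteresis — an
   overlap of the two state-space segments over which their 95% confidence
   bands are disjoint (two states for one stressor value).
2. **Early-warning indicators.** Univariate (lag-1 autocorrelation, SD,
   skewness, and their expanding-window composites) and multivariate
   (meanAR/maxAR, meanSD/maxSD, eigenCOV/maxCOV, PCA- and
   maximum-autocorrelation-factor-based indicators, mutual information)
   statistics, computed over rolling windows (50% of the series, Kendall-τ
   trend, permutation test at the 95th percentile) or expanding windows
   (running standardisation `EWS_t = (ews_t − mean)/sd`, warning at ≥2 points
   above 2σ after a 50% burn-in).
3. **Evaluation.** Warnings are scored against the ground-truth fate with a
   Bayesian hierarchical binomial model,
   `logit(π) = β_level + u_lake + u_fate + u_lake:fate` (no global intercept;
   β ~ Normal(0, 1.2) truncated to ±5.5, Exponential(1) scale priors),
   sampled by Hamiltonian Monte Carlo; a factor level beats chance when its
   95% credible interval lies above 0.5.

Because the original monitoring data are partly access-restricted, the
package ships a first-class synthetic-lake generator
(`lakeews.synthetic_lakes`) producing labelled communities for six
mechanisms: fold bifurcation with hysteresis (a grazing-type consumer model
driven past its saddle-node), step change, noise-induced shift,
threshold-like sigmoid response, smooth trend, and stationarity. Every
downstream stage is tested against these labelled conditions.

The intended users are quantitative ecologists and methodologists studying
resilience indicators who need a transparent, fully scripted pipeline from
raw long-format monitoring records to posterior estimates of warning skill.

## Worked example

```python
import lakeews.synthetic_lakes as sl
import lakeews.classify as cl
import lakeews.assessment as asmt
from lakeews.standardise import assemble_lake_dataset

lake = sl.make_lake("demo", sl.MechanismSpec("fold_bifurcation", seed=3))
ds = assemble_lake_dataset(lake.yearly["phytoplankton"], lake.drivers_yearly,
                           "demo", "phytoplankton", "yearly")
fate = cl.classify_dataset(ds)
print(f"mechanism        : {fate.mechanism}")
print(f"transition year  : {fate.transition_time:.0f}  (truth: {lake.truth['phytoplankton'].shift_time:.1f})")
print(f"bimodality BC    : {fate.evidence['bc']:.3f}")
print(f"hysteresis       : {fate.evidence['hysteresis']}")

trimmed = cl.trim_for_assessment(ds.community, {"phytoplankton": fate})
cfg = asmt.AssessmentConfig(n_permutations=1000, seed=0)
series = trimmed.matrix.sum(axis=1).to_numpy()
warning, trace = asmt.permutation_warning(series, "ar1", cfg)
print(f"pre-transition rolling ar1 tau = {trace.tau:.2f}, warning = {warning}")
```

prints

```
mechanism        : critical_transition
transition year  : 1997  (truth: 1997.5)
bimodality BC    : 0.743
hysteresis       : True
pre-transition rolling ar1 tau = -0.33, warning = False
```

The classifier recovers the constructed fold bifurcation (breakpoint within a
year of the true collapse, bimodal density distribution, hysteresis overlap in
state space), while the rolling-window autocorrelation trend on the
pre-transition community fails to warn — the kind of false negative that
motivates scoring EWS skill formally instead of assuming it.

A command-line interface mirrors the library
(`lakeews simulate|standardise|classify|assess|evaluate`); see
`lakeews --help`.

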