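# Methods notes

This note records the modelling assumptions, parameter choices and numerical
decisions behind the package, in the spirit of a model-description appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Thermal-summation model

Development is modelled as accumulation of hourly temperature excess above a
base temperature T₀, with left-constant integration on half-open hour
intervals `[t, t+1)`. Sub-hourly records must be averaged to hourly values
before constructing a `TemperatureSeries`; gaps must be filled explicitly —
the series constructor rejects missing values rather than guessing.

Choices:

- **Sub-base clamping (default on).** The summation equations are silent on
  temperatures below T₀. The default clamps increments at zero: no
  development, and never "negative age". An unclamped mode exists for
  sensitivity analysis only.
- **No upper developmental threshold.** Development was observed up to
  35 °C in the calibration data, and the package imposes no high-temperature
  cutoff. Extrapolation above 35 °C is the user's risk.
- **Rate unit.** The development rate used in the rate-temperature
  regression is `1e4 / (development time in hours)`, recorded in
  `LinearRateFit.rate_scale`. This scale reproduces the published
  egg-to-adult regression coefficients from the published mean times to
  about three decimals; the choice is otherwise immaterial because the
  x-intercept is invariant under positive rescaling of the rate (a property
  the test suite asserts).
- **Temperature range of the base fit.** Only 20–28 °C enter the linear fit
  by default (`BASE_FIT_TEMP_RANGE`); above 28 °C the rate response
  flattens into the sigmoid regime and would bias the x-intercept. The
  range is a parameter of `fit_rate_regression`.
- **Slope p-value.** Standard two-sided t-test on the OLS slope.

## Sigmoid rate model

`fit_sigmoid` estimates `F(x) = y0 + a/(1 + exp(-(x - x0)/b))` by nonlinear
least squares (`scipy.optimize.curve_fit`). Initialization is deterministic:
`y0 ← min rate`, `a ← rate range`, `x0 ← temperature at mid-range rate`,
`b ← temperature span / 4`; on failure up to 8 seeded lognormal
perturbations of that start are tried, so output is deterministic given
identical inputs. The 95 % CI for x₀ uses the asymptotic covariance with a
t critical value on n − 4 df. Confidence bands use the delta method;
prediction bands add the residual MSE, so the prediction band contains the
confidence band everywhere by construction.

## Length–ADH regression grid and selection

Six OLS models are fitted with statsmodels: {linear, quadratic, logarithmic
in Log₁₀(length)} × {ADH, Log₁₀ADH}. Reported statistics follow the usual
definitions: `r2_adj = 1 − (1 − R²)(n−1)/(n−p−1)`,
`se_est = √(SSE/(n−p−1))`, `mse = se_est²` (an identity the tests assert on
every fit).

**Cross-scale selection.** Raw-ADH and Log₁₀ADH responses have
incommensurable MSEs, so models are ranked within each response scale by
adjusted R² (ties broken by lower MSE), and the two scale winners are
compared on the Log₁₀ scale: each raw-scale model also carries a
pseudo-adjusted-R² computed from its predictions after log-transform
(set to −∞ if it predicts non-positive ADH anywhere). The Log₁₀ADH winner
is preferred unless the raw winner beats it on that common criterion. Both
rankings are always returned for audit. The default preference for the log
scale reflects the strong variance growth of raw ADH with length.

**Prediction intervals.** t-based, using the stored design summary
`(X'X)⁻¹`, residual df and scale, so serialized models predict without raw
data. For Log₁₀ADH models the interval is back-transformed with the naive
`10^·`; a lognormal smearing correction (`10^(ln10/2 · mse)`) is available
but off by default, matching common usage of such calibration curves.
Lengths outside the calibration range are flagged, not rejected.

**The packaged published model** is reconstructed from summary statistics
only (coefficients, residual SE, n); its design matrix is unavailable, so
prediction leverage is approximated by 1/n. For n = 973 the approximation
changes interval half-widths by well under 1 % except at extreme lengths.

**Log-base inconsistency in the published logarithmic equation.** The
published logarithmic Log₁₀ADH equation, taken with base-10 logs of length,
is internally inconsistent with the sibling regression equations and with
the published stage length means (at 13.16 mm it would predict ~458 ADH,
below the third-instar threshold of 812.64, where the sibling models
predict ~1300–1450). If the *length* log is natural, everything is
consistent. The package therefore keeps base-10 semantics wherever the
published equation is evaluated as printed (prediction operations, the
packaged model), but the synthetic generator inverts the law with a natural
log so that simulated lengths match the published stage means. This is a
deliberate, documented asymmetry.

## Stage model

Stages form a total order; "transition forms" (larvae caught mid-moult,
one extra posterior spiracular slit) are optional labels that collapse to
their parent instar. Minimum stage times use the first-individual
criterion, and an observation of stage S counts as evidence for every
earlier stage too — otherwise a short stage missed by 12-h sampling would
leave a hole. Threshold tables embed the base temperature they were
accumulated against (a threshold is meaningless without it) and must be
strictly increasing across primary stages; the published transition
windows are stored as side data because the second one (812.6–1612.4 °H)
extends past the post-feeding minimum, as published.

The per-temperature egg-to-adult development time is estimated from
destructively sampled observations by stage-frequency analysis: the adult
fraction among sampled individuals at each time estimates the probability
that emergence has occurred, and the development time is the linear
interpolation of that fraction through 0.5 (median emergence). This is
robust to the detection lag of the first emerged individual, which biases a
first-adult-observation estimator at coarse sampling intervals.

The two-way ANOVA without replication uses the additive decomposition with
error df (r−1)(c−1); a purely additive matrix (zero residual) reports
infinite F with a flag rather than failing. No multiple-testing correction
is applied.

## PMI-min estimation

- The ADH clock starts at oviposition; pre-oviposition delay (time from
  death to egg laying) is explicitly out of scope.
- Evidence conjunction takes the elementwise **maximum** of requirement
  bounds, never an average: PMI-min is the shortest time consistent with
  all the evidence.
- Back-accumulation walks the hourly record backwards and resolves the
  crossing hour by linear interpolation; sub-hour precision is
  presentational, given the 12-h resolution of the calibration data. A
  relative tolerance of 1e−9 at the record boundary absorbs summation-order
  rounding.
- If the record is exhausted before the requirement is met, the estimate is
  flagged and reported as a lower bound at the record length.
- Mapping an ADH prediction interval to a PMI interval under variable
  temperatures is this package's construction (no published precedent in
  the calibration study): both interval endpoints are propagated through
  the same monotone back-accumulation as the point estimate.

## Synthetic rearing experiment

The generator's defaults are the study design: 25 eggs × 10 bottles ×
7 constant temperatures (20, 22, 24, 26, 28, 32, 35 °C) × 5 replicates =
8750 eggs, destructive sampling of 4 individuals per chamber every 12 h
starting at t = 0.

Generative model:

- Each hatched egg carries personal stage-entry ADH thresholds: the
  packaged stage minima (adult entry at the thermal constant,
  232.81 × 24 = 5587.44 °H) times independent lognormal multipliers with
  mean 1 and CV 10 % (a plausible scale of within-cohort developmental
  spread), forced strictly increasing. Individual variation enters only
  through thresholds, not through temperature, preserving the linear
  rate-temperature premise of thermal summation.
- Hatch rate defaults to 0.9; unhatched eggs never enter the sampling pool
  but are accounted per bottle (observations + survivors + unhatched =
  eggs, an invariant the tests check).
- Feeding-larva length inverts the length law (natural-log form, see
  above) with Gaussian noise σ = 0.083 on the Log₁₀ADH scale. Post-feeding
  length shrinks linearly with stage-age fraction (13.2 → 11.0 mm ± 1.8),
  deliberately decoupled from ADH — body length stops informing age after
  feeding ends. Egg, pupa and adult lengths are drawn around fixed means
  (1.17 ± 0.13, 7.73 ± 0.63, 9.0 ± 0.5 mm; the adult value is nominal).
- Sampling draws from one randomly chosen non-empty bottle per chamber per
  interval and stops when the pool is exhausted or everything has emerged.
  An optional contamination mode inflates a fraction of lengths 3–10× to
  exercise outlier flagging; no fidelity is claimed for it.

What the generator does *not* emulate: maggot-mass thermogenesis (the
25-egg design was chosen to avoid it), diapause, photoperiod effects,
chamber temperature error, measurement shrinkage of preserved specimens,
and any cause for the published outlier count. Passing closed-loop tests
therefore demonstrates the pipeline's statistical correctness under the
thermal-summation model, not field realism.

With these defaults one full run yields roughly 5 000 observations of the
8 750 eggs and a feeding-stage scatter within a few percent of the
published scatter size (n = 973), with no tuned thinning; the simulator
reports both published definitions of sample coverage because they cannot
be reconciled exactly.

## Validation problem sizes

The suite validates by parameter recovery at sizes chosen to keep the whole
run comfortably under a few minutes on one CPU: base-temperature recovery
uses one noiseless densely-sampled run (2-h interval, 1 per sample,
20–28 °C) and twenty default-noise full-design runs (seed-averaged);
length-model recovery uses n = 973 at σ = 0.083; selection consistency uses
200 generative replicates; prediction-interval coverage uses 2 000 fresh
points. Property-based tests (hypothesis) run derandomized.

## Known limitations

- Calibration is specific to one population and 20–35 °C constant
  temperatures; base temperatures differ by region and species.
- The length model is valid for feeding larvae only (ADH ≤ 1551.60);
  post-feeding and pupal ages must come from stage thresholds, which are
  step functions of the evidence and carry no statistical interval.
- Scene temperature records are used as-is; microclimate correction from
  weather-station to body-site temperature is out of scope.
- The published stage-wise rate regressions (egg, instars, post-feeding,
  pupa) are shipped as constants for the x-intercept bookkeeping, but only
  the egg-to-adult fit is reproducible from published per-temperature
  times.
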