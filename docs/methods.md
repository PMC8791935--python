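# Methods

## Scope and data model

The package links three city-day panels: an ordinal policy-indicator panel
(nine indicators, country-level but stored per city), a pollutant-difference
panel y_it (Lockdown − BAU, µg/m³; daily means for NO₂/PM, daily maximum
8-h mean for O₃), and static city metadata (coordinates, population, NDVI,
built-up share, crude all-cause death rate).  The study window defaults to
1 February – 31 July 2020.  No chemistry-transport modelling is attempted:
pollutant differences are treated as given (or simulated from the
statistical model itself), and meteorology is assumed identical between the
two scenarios by construction of such counterfactual pairs.

## Stringency Index

SI = 100 × mean of the nine standardised indicator levels (level /
max_level).  This is the plain equal-weight composite; no flag-variable
adjustments are applied.  The leave-one-out variant x′ is the mean of the
remaining eight, rescaled by 100 — deliberately *not* renormalised back to
a 0–100 "full" scale, so the exact identity 9·SI = 8·SI₋ₖ + 100·z_k holds
and is tested.  Missing indicators are a validation error, never imputed:
a city without response data should be excluded, not silently filled.

## Stage-1 model

y_it = f(x_it; β + b_i) + γ₁ᵢ[DOW_t] + γ₂ NDVI_i + γ₃ BuiltUp_i + ε_it,
ε_it ~ N(0, σ²) with a single shared residual variance (configurable choice;
a city-specific variance was considered and rejected as weakly identified at
≤ 50 sites).

Identifiability is arranged so that the model genuinely has no intercept:

* **Anchored natural spline.**  f uses a natural cubic basis with 4 df —
  three interior knots at the pooled 25/50/75% SI quantiles, boundary knots
  at 0 and the maximum observed SI, linear beyond the boundary — with the
  basis row at SI = 0 subtracted from every row.  Any fitted curve passes
  exactly through (0, 0).  Tied quantiles (step-like SI trajectories) are
  repaired by falling back to evenly indexed distinct observed values.
* **Sum-to-zero day-of-week effects** per city (6 free parameters through a
  contrast matrix); otherwise each city's DOW block would absorb an
  intercept.
* **z-scored NDVI and built-up area** across cities (the source scale is
  arbitrary); their two slopes are the only city-constant terms.

Each of the four coordinates of b_i gets an independent zero-mean Matérn
Gaussian-process prior over great-circle (haversine) distance in km,
smoothness ν = 1 (the standard 2-D choice), with its own (range, sd)
hyperparameters.  With ≤ 50 sites the exact dense covariance is used —
no mesh, no sparse approximation.

### Priors

* Unstructured coefficients (β, DOW, covariates): Normal(0, 10⁶), a
  near-flat proper prior kept for numerical stability.
* Matérn (range, sd): penalized-complexity priors defined by tail
  probabilities P(range < range₀) = α_r and P(sd > sd₀) = α_s; defaults
  range₀ = 500 km, α_r = 0.5, sd₀ = 10 (coefficient scale), α_s = 0.05 —
  weakly informative at continental scale.
* Residual σ: flat on log σ.

### Inference engine

Given the hyperparameters θ = (log σ, {log range_k, log sd_k}) the model is
linear-Gaussian, so the coefficient vector is integrated out analytically
and inference works on the marginal posterior of θ:

1. maximise log marginal likelihood + log PC priors over θ (L-BFGS-B on the
   log scale, bounded);
2. Laplace-approximate the θ posterior with a central-difference Hessian at
   the mode (non-positive curvature directions are clipped to a floor,
   yielding wide bound-limited uncertainty rather than a failure, and are
   reported in the diagnostics);
3. draw θ from the Laplace Gaussian (clipped to bounds) and, for each draw,
   sample the coefficients exactly from their conditional Gaussian.

Coefficient draws use antithetic ± pairs around each conditional mean, so
posterior *means* carry no coefficient-level Monte-Carlo error — only the
hyperparameter mixture varies.  This matters because the shared spline
block and the per-city deviation blocks are exactly collinear (only β + b_i
is data-identified; the split is prior-driven), which would otherwise
inflate the Monte-Carlo error of reported means.  For the same reason the
conditional solve retries with an escalating diagonal jitter when σ is
so small that the prior no longer regularises the collinearity numerically.

Defaults: 1000 posterior draws, optimizer cap 200 iterations, Hessian step
0.05 (log scale).  A seed is required, stored in the diagnostics.
Non-convergence (optimizer failure or an indefinite Hessian) sets
`converged: False` and warns; it is never silent.

### Outputs

`predict_curve` isolates f: the average curve uses β only, a city curve
β + b_i; covariate and DOW terms are excluded.  The default grid is SI
0–80 because higher values are rarely observed; beyond the fitted boundary
the curve is flagged as a linear extrapolation.  Bands are empirical
2.5/97.5 percentiles of draw-wise curves.  `predict_at_si` evaluates the
same object per city at one SI value.

## Stage-2 model

One fully independent fit per indicator (fresh hyperparameters), adding
(α + a_i)·z_it with a_i spatially structured exactly like the b
coordinates, and replacing x by x′.  The spline knots are re-derived from
the x′ distribution (x′ is a different variable).  A policy never
implemented in the data (z ≡ 0) is a degenerate-design error.  α is
reported per unit of standardised z — the full-stringency effect — and is
invariant to rescaling the indicator's ordinal range.

**Collinearity caveat.**  European governments moved most policies almost
in lockstep, so z and x′ are strongly collinear and the α posteriors are
wide; with perfectly lockstep synthetic policies the intervals widen
further (tested).  Two consequences measured on synthetic data: with the
experiment's data generation fixed, α recovery is excellent (≈ 0.3% error
at full size) and insensitive to the inference seed; across independently
regenerated studies the recovery error varies between roughly 10% and 40%,
because the split between the policy term and the leave-one-out spline —
and between α and the mean of the spatial field a — is partly prior-driven.
Per-policy estimates should be read as adjusted associations under strong
collinearity, not isolated causal effects.

## Health impact assessment

d_it = (m_i / 365.25) · p_i · (1 − e^(−ξ y_it)) with m_i the *annual* crude
death rate — the daily baseline is m_i/365.25 · p_i; this unit convention
rescales every burden and is therefore stated prominently.  Burdens use the
observed y_it directly, independent of the stage-1 fit, with same-day
exposure and no lag.  ξ = ln(RR)/increment and its standard error
(ln(ci_hi) − ln(ci_lo))/(2·1.96·increment) come from a user-supplied risk
configuration; the bundled defaults are placeholders, not literature values.

Monte-Carlo intervals: n_mc = 1000 draws ξ⁽ᵏ⁾ ~ N(ξ̂, se²), one draw per
iteration applied to all cities (inducing the correlated city intervals a
summed total requires), percentiles by the inclusive linear-interpolation
convention.  The point estimate always uses ξ̂ itself.  City totals and
Monte-Carlo replicates share one fixed summation path, so se = 0 collapses
intervals onto the point estimate bit-for-bit.  Totals are reported per
pollutant separately; no multi-pollutant overlap correction is attempted
(the per-pollutant avoided deaths partially overlap and must not be added).

The report table keeps cities lacking a death rate as NA rows — included
in the population column, excluded from burden TOTALs — matching how the
published 47-city table handles its one such city.

## Synthetic data generator

The generator emulates the observed study's structure, not any specific
city: coordinates uniform over a Europe-like box (lon −10..30, lat 35..65),
populations log-uniform 10⁵–10⁷, crude death rates uniform 0.008–0.012 per
person-year, NDVI 0.1–0.6 and built-up share 0.05–0.6.  Policy trajectories
follow the observed shape: zero until a country-specific onset about a
fifth into the window (early/mid March for the default window), a stepwise
jump to near-maximum within about ten days, a plateau, and stepwise
relaxation from a country-specific date (mid-May onwards), giving at most
five change-points per indicator series.  Pollutant panels are drawn from
the stage-1 structure itself with defaults chosen as a plausible NO₂-like
study: a true fixed curve ≈ −6.5·(SI/80)² µg/m³ (monotone, steeper at high
stringency), Matérn deviations with range 600 km and sd 0.8, per-city
DOW effects of sd 0.3 centred to zero, covariate slopes −0.5 and +0.8 per
z-score, residual sd 1.5 µg/m³.  All stochastic steps are reproducible from
a single seed, and every coefficient is recorded in a `SyntheticTruth`.

What the generator does *not* emulate: temporal autocorrelation of
residuals, seasonal chemistry (the springtime O₃ titration pattern),
heteroscedastic or heavy-tailed noise, and measurement structure of any
real modelling system.  Passing recovery tests therefore demonstrates that
the estimation machinery recovers the assumed data-generating process at
realistic size and noise — not that the model is correctly specified for
real counterfactual pollution fields.

## Experiment sizes and numerical choices

Recovery experiments run at the study's own scale (47 cities × 182 days)
for both stages; the null calibration and simulation-based calibration use
20 replicates at 10 cities × 90 and × 60 days respectively, sizes chosen to
keep the full suite in a few minutes while leaving the conclusions
unchanged at larger sizes.  Matérn matrices carry a 10⁻⁸·sd² diagonal
jitter; percentile conventions are linear-interpolation throughout;
distances are great-circle km (no projection).  The published reference
table bundled with the package reproduces its printed TOTAL row by direct
summation of the printed city rows, up to the last printed digit (the
published TOTALs were computed before the city cells were rounded, and the
printed population total itself is off by two persons).

## Known limitations

* The Laplace approximation can understate hyperparameter uncertainty in
  flat directions (ranges of weakly identified fields); such directions are
  curvature-clipped and surfaced via diagnostics rather than hidden.
* Mid-range SI (≈ 20–40) is sparsely observed in step-like trajectories, so
  the corresponding spline coordinates — and hence per-city orderings that
  weight them — are weakly identified at default noise levels.
* Per-policy effects inherit the lockstep-collinearity identification
  problem described above.
* The HIA is short-term, all-cause, same-day only: no cause-specific
  outcomes, no long-term risks, no exposure lags, no risk heterogeneity
  across cities.
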