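# lockdownair

Did stricter COVID-19 lockdowns clean the air, and how many deaths did that
avoid?  `lockdownair` is a reusable pipeline for answering that question the
way it was posed for 47 European cities in spring 2020: relate daily
modelled pollutant changes between a lockdown and a business-as-usual (BAU)
emission scenario to the strictness of government responses, decompose the
effect by individual policy, and translate the concentration changes into
short-term attributable mortality.  It is aimed at environmental
epidemiologists and air-quality analysts who have (or want to emulate)
city-day panels of pollutant differences and policy indicators.

## The models

**Stringency Index (SI).**  Nine ordinal policy indicators (school and
workplace closing, event cancellation, gathering limits, public-transport
closure, stay-at-home orders, movement restrictions, international travel
controls, information campaigns) are each standardised to [0, 1] by their
maximum level and averaged; the mean is rescaled to 0–100.  A leave-one-out
SI (x′) drops one indicator from the mean of the remaining eight.

**Stage 1 — exposure–response.**  For pollutant change y_it (µg/m³,
Lockdown − BAU) of city i on day t with daily SI x_it:

    y_it = f(x_it; β + b_i) + γ₁ᵢ[DOW_t] + γ₂ NDVI_i + γ₃ BuiltUp_i + ε_it

f is a natural cubic spline (4 df, knots at the pooled 25/50/75% SI
quantiles) *anchored at SI = 0*, so the model has no intercept: no policy
response implies no pollutant change.  Each coordinate of the city
deviations b_i carries an independent Matérn Gaussian-process prior over
great-circle distance with penalized-complexity (PC) hyperpriors; γ₁ᵢ are
city-specific day-of-week effects constrained to sum to zero.  Inference is
an INLA-style marginal-likelihood scheme: coefficients are integrated out
analytically, the hyperparameter posterior is Laplace-approximated at its
mode, and exact conditional Gaussian draws are mixed over it.

**Stage 2 — per-policy effects.**  One independent model per indicator adds
a linear term (α + a_i)·z_it, with z the standardised policy level and a_i
spatially structured like b_i, adjusting for the spline of the leave-one-out
SI.  α is the expected change at the policy's maximum level.

**Stage 3 — health impact.**  With ξ the log relative risk of death per
µg/m³ from published multi-country studies, daily burdens are

    d_it = (m_i / 365.25) · p_i · (1 − e^(−ξ·y_it)),

summed per city and overall for February–July; negative totals are avoided
deaths.  Uncertainty comes from 1000 Monte-Carlo draws ξ⁽ᵏ⁾ ~ N(ξ̂, se²)
(one draw per iteration shared across cities), with empirical 2.5/97.5
percentile intervals.

A synthetic-data module generates cities, policy panels and pollutant
panels with exactly this structure and a recorded ground truth, so the
whole pipeline is testable without any external download.

## Worked example

```sh
lockdownair simulate --n-cities 10 --seed 5 --out demo
lockdownair fit --pollutant no2 --cities demo/cities.csv --si demo/si.csv \
    --pollution demo/pollution.csv --seed 3 --n-draws 300 --out demo/fit
```

prints (abridged):

```
Stringency-pollution model: no2
  cities: 10   observations: 1820
  converged: True

  coefficient        mean [95% CrI]
  beta[0]         -1.333 [  -2.867,    0.211]
  beta[1]         -5.346 [  -6.528,   -4.081]
  beta[2]         -9.483 [ -10.357,   -8.747]
  beta[3]         -9.937 [ -10.605,   -9.254]
  gamma2 (NDVI)    -0.535 [  -0.654,   -0.416]
  gamma3 (BU)       0.880 [   0.756,    1.012]
  residual sd       1.455 [   1.407,    1.510]
  b0.range_km   1625.983 [ 260.412, 5632.510]
  b0.sd            1.366 [   0.723,    2.495]
  ...
```

The four `beta` values are the spline coefficients of the average
exposure-response curve — increasingly negative, i.e. stricter lockdowns
remove more NO₂ (the synthetic truth here reaches about −6.5 µg/m³ at
SI = 80).  `gamma2`/`gamma3` are the greenness and built-up covariate
slopes per z-score unit, `residual sd` the day-to-day noise (truth: 1.5
µg/m³), and each `b*.range_km`/`b*.sd` the Matérn range and spread of one
spatial field of city deviations.  `demo/fit/curve.csv` holds the average
curve with its 95% band; `city_change_si80.csv` the per-city change at
SI = 80.

```sh
lockdownair hia --pollution demo/pollution.csv --cities demo/cities.csv \
    --n-mc 500 --seed 9 --out demo/hia
```

```
no2: total -279.5 (-357.8; -201.3) deaths
```

i.e. over the six simulated months the modelled NO₂ reductions would have
avoided about 280 deaths across the ten synthetic cities (95% interval 201
to 358), using the bundled placeholder relative risks — real analyses must
supply their own risk configuration (`--risks risks.yaml`).
`lockdownair report` writes the city-by-city table with a TOTAL row, and
`lockdownair policies` the nine per-policy effect estimates.

The same objects are available as a library
(`StringencyPollutionModel(...).fit(seed=...)` →
`PollutionResults.summary() / predict_curve() / predict_at_si() /
plot_curve()`, `PolicyEffectModel`, `HealthImpactAssessment`,
`generate_dataset`).

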