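# Methods

`washcast` is a country-level simulation model for forecasting access to
improved and piped water, WASH-attributable mortality and deaths, household
water-collection time, and the economic losses these outcomes impose, with
Monte Carlo propagation of parameter uncertainty and a trajectory-based
grouping of countries. This note records the model, its assumptions, the
numerical choices, and what the synthetic study conditions do and do not
establish.

## Model

The model has three stages.

**1. Estimation.** Three reduced-form panel equations are fit on a
country-year panel (pooled least squares, country-clustered robust standard
errors; a random-country-intercept estimator is available behind
`estimator="random_effects"`):

- coverage (fraction, fit separately for the improved and piped
  definitions) on ln *lagged* per-capita GDP and urban share — coefficients
  `kappa_Y`, `kappa_urban` per definition;
- WASH mortality rate (deaths/1,000/yr) on ln GDP and both coverage
  fractions — `alpha_Y`, `beta_imp`, `beta_piped`, plus `gamma_temp` when an
  informative temperature series is present;
- one-way collection time (minutes) on ln GDP and urban share — `theta_Y`,
  `gamma_urban`.

All coefficients are semi-elasticities: outcomes stay in natural units
while income enters in logs. Coverage is fit in fraction units,
untransformed; no logit or similar boundary transform is applied (a
deliberate choice — the linear recursions below consume linear marginal
effects, and the explicit clipping handles the bounds). Controls
(fertility, literacy, governance scores, survey-source indicators, …) enter
as arbitrary named columns rather than hard-coded region dummies. Rows with
missing covariates are dropped listwise and counted in the fit report.
These are associations used for forecasting, not causal effects.

**2. Projection.** From each country's last observed year, outcomes are
stepped annually by elasticity-weighted driver changes:

    coverage[t]  = coverage[t-1] + kappa_Y dlnY[t] + kappa_urban dUrban[t]
    mortality[t] = mortality[t-1] + alpha_Y dlnY[t] + beta_imp dImp[t]
                   + beta_piped dPiped[t] + gamma_temp dT[t]
    time[t]      = time[t-1] + theta_Y dlnY[t] + gamma_urban dUrban[t]

with deaths = rate/1,000 × population. The income driver is the change in
**ln** GDP per capita: the fitted coefficients are per log-income unit, so
a level change would be dimensionally inconsistent (`dy_mode="level"`
preserves the literal level reading for sensitivity). GDP growth itself can
carry a climate channel: annual log growth is shifted by
`climate_gdp_coeff` per °C of annual warming. `gamma_temp` in the mortality
recursion is an external (literature-sourced) coefficient unless the panel
itself identifies it; the temperature channel refuses to run without one.

Bounds are enforced *after each annual step*: coverage clipped to [0, 1]
(piped additionally capped at improved, since the definitions are nested),
mortality and collection time floored at 0. Every clip/floor event is
flagged in the output and counted in the run manifest, because bound
handling is a modelling decision that should be auditable. Pre-bounding,
each recursion under constant drivers reduces exactly to baseline +
t × increment, which is the oracle the tests assert to 12 significant
digits.

**3. Valuation.** Two loss flows per country-year, in constant currency
(1990 international dollars), undiscounted:

- health: `H = Pop × (rate/1000) × VSL × (1 + f_morb)`, with
  `VSL = vsl_ref × (y/y_ref)^elasticity` (power-law benefit transfer;
  default elasticity 1.0; `vsl_ref`/`y_ref` are required configuration with
  no currency defaults) and morbidity a fixed fraction `f_morb` of
  mortality losses (base 0.25, sensitivity 0.10–0.40) in lieu of incidence
  data;
- time: `T = (Pop/hhsize) × 2 one-way trips/day × (minutes/60) × v × 365`,
  where the hourly opportunity cost `v` is `time_value_fraction` (default
  0.5) of bottom-80% per-capita income — `(share_b80 × gdp_pc)/0.8` —
  divided by `work_hours_per_year` (default 2,000). The fraction and work
  hours are this package's own round-number defaults.

Income share and household size are carried forward at their last observed
values; the model projects neither. `total = H + T` and
`morbidity = f_morb × mortality` hold exactly at every cell.

## Monte Carlo design

Per draw: each country's average annual growth rate is drawn independently
from N(3.7%, 1.3%) — the historical cross-country spread of sub-Saharan
growth — and held constant over the horizon; each fitted elasticity is
drawn from a normal with sd implied by its 95% CI ((hi−lo)/3.92), truncated
to that CI (family configurable; draws may cross zero if the CI does — no
sign-preserving truncation); `f_morb` uniform over its bounds; the climate
coefficient over its literature bounds. Negative growth draws are allowed
(the base distribution has negligible negative mass). 1,000 realisations is
the reference ensemble size; the bundled analysis uses 200 to keep the
run short, which widens quantile noise but changes nothing structurally.

Ensembles are summarised by pointwise per-year quantiles (interquartile by
default; trajectory-wise bands are deliberately not computed) of aggregate
outputs: population-weighted mortality, collection time and improved
coverage, and summed deaths and losses. A failed draw is recorded with its
exception and skipped, never silently dropped.

Variance attribution uses squared standardized regression coefficients
(SRC): the output is regressed on the standardized draws and each
parameter's share is its squared standardized coefficient, with the
unexplained remainder reported as a residual. SRC is appropriate here
because the simulator is nearly linear in its parameters over the sampled
ranges (residual shares in the bundled analysis are ~1%); it is not a
Sobol' decomposition and will misattribute strongly interacting inputs.
Constant (degenerate) parameters get a zero share; rank-deficient draw
matrices are rejected naming the collinear parameters.

## Trajectory groups

Countries are classified from two numbers — the baseline (last observed)
and terminal (projected, default 2050) mortality rates: group 4 if baseline
< 0.5; group 3 if baseline in [0.5, 1.0) and terminal < 0.1; group 1 if
baseline ≥ 1.0 and terminal ≥ 1.0; group 2 otherwise. The thresholds encode
the narrative definitions of the four trajectories (high-and-stuck,
moderate-slow-decline, moderate-to-negligible, low-throughout) and are all
configurable because no formal rule exists; classification uses the
base-case trajectory, not ensemble quantiles. Group aggregates are
same-year-population-weighted means for intensive fields and sums for
extensive ones, so group deaths and losses conserve the all-country totals
exactly.

## Synthetic study conditions

No real JMP/UN/WHO/World Bank extract ships with the package; the
`synthetic_data` module generates panels whose structural equations mirror
the three estimating equations with user-set true coefficients, so
parameter recovery is checkable. Defaults: 40 countries, 1995–2014, GDP₀
log-uniform on $500–5,000, growth N(3.7%, 1.3%), urban share starting at
0.15–0.55 drifting ~0.5 pp/yr (with per-country heterogeneity — needed so
urbanisation is not a pure common time trend), population 1–50 M growing
1.5–3%/yr, a common 0.02 °C/yr warming ramp, and Gaussian per-equation
noise (coverage 0.02, mortality 0.10, collection 2.0). True elasticities
default to values that keep every outcome interior to its bounds
(mortality ~0.9–3.1 deaths/1,000, collection ~10–40 min), magnitudes chosen
to resemble sub-Saharan conditions.

Two generator design points worth recording:

- **Piped coverage** is generated linearly from its *own* coefficients with
  a lower intercept, then capped at improved. A multiplicative
  sub-share construction would also guarantee nesting but makes the piped
  semi-elasticities products of the improved ones, i.e. not independently
  recoverable; the cap is slack at the default parameters, so noise-free
  recovery stays exact.
- **"Noise-free" is per equation.** With *all* noise at zero, coverage is
  an exact linear function of income and urban share, making the mortality
  design matrix rank-deficient; recovery tests therefore zero only the
  equation under test, leaving the coverage regressors their own variation.

What the synthetic conditions do not emulate: real-world measurement error
structure, spatially correlated shocks between countries, joint
distribution of the governance/fertility controls (independent draws,
documented as such), survey-revision discontinuities in coverage series,
and catastrophic events (floods, droughts) — the recursions are smooth by
construction. Passing tests establish internal correctness (recovery,
exactness, conservation, reproducibility), not external predictive
validity for any real country.

## Numerical choices and degenerate inputs

- Income lag in the coverage equation is exactly one panel period.
- Cluster-robust SEs require ≥ 2 countries; single-country panels fall back
  to classical SEs.
- Near-collinear coverage columns (|corr| > 0.999 or design condition
  number > 1e8) trigger a warning with the condition number rather than an
  error — the fit is returned but flagged as not separately identified.
- Panel CSV round-trips write floats with `%.17g`, preserving doubles
  bit-for-bit in practice (tested to ≥ 12 significant digits).
- All randomness derives from integer seeds through NumPy `SeedSequence`
  substreams (generator: country attributes / panel noise / scenario;
  pipeline: a dedicated ensemble substream), so identical configuration and
  seed reproduce byte-identical outputs.
- Truncated-normal sampling inverts the CDF at uniform draws, keeping the
  draw count per parameter fixed regardless of truncation mass.
- Quantiles are computed with NumPy's default linear interpolation and are
  monotone in probability by construction.

## Known limitations

- Linear recursions with clipping can sit at a bound indefinitely; there is
  no mean reversion or saturation curve near full coverage.
- The mortality recursion passes both dImproved and dPiped as written even
  though piped is a subset of improved, so the two coverage effects
  partially double-count a piped expansion; this mirrors the estimating
  equation but is worth remembering when interpreting `beta_piped`.
- Variance shares are regression-based, not variance-decomposition-exact
  for nonlinear interactions.
- Losses are annual flows in constant currency with no discounting and no
  aesthetic/quality-of-life component.
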