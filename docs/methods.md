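# Methods

This note documents the model implemented by `adtcea`: its structure and
assumptions, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical and design choices made where
the design was genuinely open.

## Model structure

The model is a cohort-level Markov process over nine mutually exclusive
health states on 28-day cycles (matching the dosing interval of both
drugs), run for floor(30 × 365.25 / 28) = 391 maintenance cycles after the
initial cycle, i.e. just under 30 years.  The state chain reconstructs the
treatment pathway for Chinese practice: first-line castration therapy;
on PSA recurrence, anti-androgen addition, then anti-androgen withdrawal;
at withdrawal failure a 35% / 65% split between going directly to
abiraterone (the chemotherapy-skip branch) and docetaxel; docetaxel
failures proceed to abiraterone; abiraterone failures to a bundled
"continued treatment" state, then supportive and finally palliative care.
Death is absorbing and reachable from every state.  The chain and the
split fractions are all ordinary `ParameterSet` fields, so alternative
readings of the pathway are runnable without code changes.

Two deliberate resolutions of ambiguity in the pathway: (a) all docetaxel
leavers proceed to abiraterone rather than partly to supportive care; (b)
palliative care exits only through background mortality scaled by the
post-progression hazard ratio — there is no separate terminal transition
rate.  Both are configuration defaults, not hard-coded behaviour.

## First-line progression

Time to PSA recurrence on the reference (leuprorelin) arm follows a
parametric survival curve.  Five families are implemented with these fixed
parameterizations (t in days):

| family      | S(t)                          | notes                      |
|-------------|-------------------------------|----------------------------|
| exponential | exp(−λt)                      | 1 parameter                |
| Weibull     | exp(−λt^γ)                    |                            |
| log-logistic| 1/(1 + λt^γ)                  | the form used in the base case |
| log-normal  | 1 − Φ((ln t − μ)/σ)           |                            |
| Gompertz    | exp(−(λ/γ)(e^{γt} − 1))       | plateaus at e^{λ/γ} if γ<0 |

Fitting maximizes the right-censored log-likelihood
Σ δᵢ ln h(tᵢ) + Σ ln S(tᵢ) and the family is selected by minimal
AIC = 2k − 2 ln L, with ties broken toward fewer parameters and then a
fixed family order.  The treated (degarelix) arm is derived from the
reference curve by proportional hazards on the cumulative-hazard scale,
S_deg = S_leu^HR; fitting each arm independently from two datasets is also
supported.  Per-cycle progression probabilities are conditional
probabilities p_i = 1 − S((i+1)c)/S(ic), which telescope exactly back to
the survival ratio — this identity is enforced by property tests at 1e−10.

The default curve in the fixture (λ = 7.7e−5, γ = 1.3, median time to
progression ≈ 4.0 years; HR = 0.66) is a synthetic placeholder: the source
model reports that a log-logistic curve was selected but not the fitted
parameter values, nor the numeric PSA-recurrence hazard ratio.  Both are
provenance-tagged `synthetic` and were chosen once as clinically plausible
magnitudes (a several-year median progression-free interval on first-line
ADT; a moderate antagonist advantage).

## Background mortality

An age-specific annual mortality table is smoothed with a three-parameter
logistic curve of age, q(a) = L/(1 + e^{−k(a−a₀)}), fitted by least
squares; a raw-table mode with linear interpolation is available as a
fallback.  Annual probabilities convert to cycle probabilities assuming a
constant hazard within the year:

p = 1 − exp(−HR · (−ln(1 − q)) · c/365.25),

with the hazard ratio applied on the hazard scale (a probability-scale
multiplier could exceed 1).  Compounding 365.25/c cycles at HR = 1
recovers the annual probability exactly.  The post-progression mortality
hazard ratio 2.39 applies by default to every state after first-line
therapy; whether it should cover all post-progression states or only
metastatic ones is ambiguous in the source, so a per-state override map is
exposed.  Attained age is 68 + cycle·28/365.25, and the fitted curve is
clamped to its table's age range (beyond the last age the last value
holds).  Fatal cardiovascular adverse events are costed and
utility-decremented but add no excess mortality: background mortality is
all-cause and already contains cardiovascular deaths.

## Transition bookkeeping

Within a cycle, death competes with pathway exits: for a state with exit
probability e and death probability p_d, the row is
stay = (1−e)(1−p_d), move = e·split·(1−p_d), die = p_d.  Rows are
validated to sum to 1 within 1e−9 and the engine checks mass conservation
and death monotonicity on every trace.  An individual-level
microsimulation of the identical process ships alongside the cohort
engine as a validation oracle; the acceptance suite compares the two at
100,000 patients within three binomial standard errors.

## Costs, utilities, accrual

Per-cycle state costs combine: arm-specific drug acquisition (degarelix
8,900 yuan loading dose at cycle 0 and 3,200 from cycle 1; leuprorelin
1,389.29 per cycle — the mean of one originator and two generic prices —
plus 28 days of anti-androgen flare cover at 169.37/day with the first
dose only), daily-priced second-line drugs charged at daily cost × 28,
bundled per-cycle management costs (25,200 / 7,500.92 / 5,804.82 yuan for
post-abiraterone, supportive and palliative care), per-item administration
costs attached through a per-state frequency map, and expected
adverse-event costs (per-cycle incidence × severity-mix-weighted event
cost).  Castration therapy continues to be charged through the
anti-androgen states (configurable), reflecting that anti-androgen
addition supplements rather than replaces ADT.  The enzalutamide daily
price is carried in the cost set but unused by the default state-cost map
(the post-abiraterone bundle already covers that phase).

Utilities are 0.90 (first line), 0.80 (both anti-androgen states), 0.69
(chemotherapy, abiraterone, and the post-abiraterone phase), 0.40
(supportive and palliative care); adverse events subtract their decrement
for one cycle per event, in expectation.  Each cycle accrues
utility × 28/365.25 QALYs, discounted at (1+r)^{−t(years)} with separately
configurable cost and effect rates (both default 0.05/year).

Accrual convention: a trace has N+1 rows (initial row plus N cycles); the
first N rows each represent a cycle lived and accrue cost and QALYs, the
terminal row is a snapshot and accrues nothing, keeping total accrued time
at 391 × 28 d ≈ 29.97 y within the 30-year horizon.  Half-cycle correction
is off by default and, when enabled, applies trapezoid weights
(0.5, 1, …, 1, 0.5) over all rows.

Adverse-event incidences per cycle (order 1e−3–1e−4, cardiovascular risk
slightly higher on the agonist arm, consistent with the comparative safety
literature) and administration-visit frequencies are synthetic
placeholders: the source obtained these from expert surveys and trial
safety data without printing them.  Event costs, severity categories and
disutility decrements are the published values; the severity/treatment mix
within a category defaults to equal weights.

## Incremental statistics

ΔC, ΔE, ICER = ΔC/ΔE, INB = wtp·ΔE − ΔC, and ICER/GDP-per-capita are
computed per comparison.  ΔE = 0 yields a labelled "undefined" ICER (NaN,
never an exception); ΔC < 0 with ΔE > 0 is labelled "dominant", the
reverse "dominated".  The default willingness-to-pay is 3 × GDP per capita
(3 × 80,976 = 242,928 yuan/QALY, 2021).  Reporting rounds yuan to integers
and QALYs to three decimals; internal arithmetic is never rounded.

## Sensitivity analyses

* **One-way.**  Each parameter takes exactly two extra full model
  evaluations (low, high), all others at base; rows are stable-sorted by
  descending ICER range.  Default ranges: ±20% for cost parameters, ±10%
  for efficacy parameters (response-rate perturbations capped at 1),
  utilities ±10% capped at 1, cost discount rate 0–8%.
* **Scenarios.**  Arbitrary dot-path edits on a deep copy; the base set is
  never mutated.  The standard battery: 10-year horizon, doubled
  comparator dose (7.5 mg priced as two 3.75 mg doses), and the
  threshold-price scenario.
* **Threshold price.**  Bisection on a price path assuming ICER
  monotonicity over the bracket (default 0 to twice the base price),
  stopping at |ICER − target| ≤ 1 yuan/QALY or bracket width < 0.01 yuan.
* **Probabilistic.**  Families follow standard cost-effectiveness
  practice, since the source does not state its choices: gamma for costs,
  beta for utilities and probabilities, log-normal for hazard ratios,
  moment-matched to the base value with a default 20% relative standard
  error (per-parameter configurable).  Draws falling outside a parameter's
  domain are rejected and redrawn up to a cap, then raise.  Default 5,000
  iterations; the CEAC is evaluated on a 0–300,000 yuan grid in 1,000-yuan
  steps, covering 1×–3× GDP per capita.  Random-number contract: one root
  seed; the stream for (iteration, parameter) derives from the seed, the
  iteration index and a hash of the parameter path, so adding or removing
  a parameter leaves all other draws unchanged.

## Synthetic-data generator

`gen_survival` draws two-arm right-censored progression data by inverse-CDF
sampling (for the log-logistic, T = ((1−U)/(λU))^{1/γ}); the treated arm
samples from S_ref^HR.  Censoring is administrative at 364 days — a
12-month trial window of thirteen 28-day cycles — plus a 20% uniform
dropout fraction.  `gen_life_table` evaluates the logistic mortality curve
on integer ages (defaults L = 0.7, k = 0.09, a₀ = 97 over ages 40–100,
giving q(68) ≈ 0.05 — a plausible elderly-male schedule).  `gen_fixture`
assembles the complete parameter set with a per-field provenance map
separating `printed` from `synthetic` values, so tests can assert on
published values only.

What the generator does *not* emulate: PSA-level trajectories (events are
modelled only as times, not as threshold crossings of a biomarker),
patient-level covariate heterogeneity, interval censoring, or real
life-table irregularities (accident humps, cohort effects).  Passing tests
therefore demonstrate internal correctness of the estimators and the
engine under the stated generating processes — not that the placeholder
parameter values reproduce any particular published total.

## Numerical choices

* MLE by Nelder-Mead from three starting values on log-transformed
  positive parameters (the Gompertz shape stays untransformed so it can go
  negative), followed by a BFGS polish with analytic gradients and a final
  root-find on the score equation — likelihood *differences* near the
  optimum drop below floating-point noise while the analytic gradient
  stays resolvable, and the root-find is what lets the exponential MLE hit
  the events/exposure closed form to 1e−8.  Non-convergence from every
  start raises; all-censored data raises.
* Logistic mortality fitting uses bounded least squares
  (`scipy.optimize.curve_fit`) with data-driven starting values; it
  requires ≥ 4 ages and at least one non-zero qx.
* AIC ties break to fewer parameters, then the fixed family order.
* Degenerate inputs are labelled or raised, never silently patched:
  zero survival at a cycle start raises; ΔE = 0 labels the ICER undefined;
  an unbracketed threshold target raises.

## Limitations

* The absolute base-case totals depend on the synthetic placeholders and
  are not comparable to any published table; only the printed-input
  arithmetic (price averaging, GDP multiples, threshold-price percentage)
  is exactly reproducible.
* No societal-perspective costs, no price-year inflation adjustment, no
  treatment switching or re-challenge, no correlated PSA draws, no value-
  of-information analysis.
* The cohort engine has no tunnel states: per-cycle exit rates imply
  geometric sojourn times, which is the standard reading of per-cycle
  response rates but cannot reproduce the (mutually inconsistent) printed
  mean response durations; the per-cycle rates are taken as authoritative.
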