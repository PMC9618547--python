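# Methods

## The decision problem

Spinal muscular atrophy (SMA) type I is an autosomal-recessive motor
neuron disease presenting before six months of age; untreated infants
never sit independently and have a median survival around one year
under supportive care, with most eventually depending on permanent
assisted ventilation (PAV). Two disease-modifying therapies exist: the
antisense oligonucleotide nusinersen (four intrathecal loading doses
within two months, then maintenance every four months for life) and
the one-time gene-replacement therapy onasemnogene abeparvovec
(AVXS-101). Both are extremely expensive, so the policy question is
their cost per quality-adjusted life year (QALY) gained relative to
standard of care (SOC), and — for the one-off therapy — the
acquisition price at which it would meet a given willingness-to-pay
(WTP) threshold.

## Model structure

A Markov cohort model with five health states:

* **not sitting, PAV-free** — SMA type I, the entry state;
* **sitting independently** — milestone achieved, type II-like prognosis;
* **walking independently** — milestone achieved, type III-like prognosis;
* **PAV** — permanent assisted ventilation;
* **dead** — absorbing.

Cycle length is one month; the horizon is 100 years (1200 cycles); the
cohort enters at age 0 entirely in the not-sitting state. Transitions
allowed: not-sitting → {sitting, walking, PAV, dead, stay}; sitting,
walking and PAV → {dead, stay}. Milestone states cannot be lost
(treatment effects are assumed durable after the trial window, there
being no long-term relapse evidence either way).

Costs (2020 Australian dollars) and effects are both discounted at 5%
per year with annual compounding, `(1.05)^(-t)`. State membership per
cycle is credited as the average of the start- and end-of-cycle
occupancy (trapezoidal half-cycle correction) and discounted at
mid-cycle time; drug doses are discounted at their exact dose time.

### Transition probabilities

* **Not-sitting → death / PAV**: constant monthly probabilities
  derived from the pivotal-trial arms — SOC 0.0532 / 0.0625, treated
  arms 0.0184 / 0.0355. They are applied as direct per-cycle
  branch probabilities.
* **PAV → death**: 0.0146 per month, from published ventilation
  survival.
* **Sitting → death**: a Weibull survival model with published
  parameters λ = 0.0006, p = 1.9613, converted to per-cycle
  probabilities by the conditional identity
  `q_k = 1 − S(t_{k+1})/S(t_k)` evaluated at cohort age. Two readings
  of the printed parameters are supported: `scale_months`,
  `S(t) = exp(−(λ·t_months)^p)` (λ a scale rate per month), and
  `rate_years`, `S(t) = exp(−λ·t_years^p)`. The month-scale reading is
  the default: it is the only reading that reproduces the published
  discounted cohort results (the year-rate reading understates
  treated-arm QALYs by 10–13%), and its implied survival (98% at 20
  years) is compatible with reported long-term type II survival.
* **Walking → death**: background population mortality from a life
  table (monthly probability rescaled from annual q_x at the cohort's
  current integer age).

### Milestone schedule

Trial end-of-follow-up proportions define who reaches a milestone:
8% of the nusinersen cohort reach sitting within the 13-month trial
window; 9/12 of the gene-therapy cohort reach sitting and 2/12 reach
walking within its 24-month window (during which no deaths or PAV
were observed, so those exits are suppressed in that arm's window).
The walking milestone is routed directly from the not-sitting state so
that milestone states remain exit-only.

Within-window timing is not published. Two allocation rules are
implemented: `immediate` (the full milestone fraction moves in the
first cycle) and `uniform` (a constant per-cycle probability solved by
root-finding so the cumulative inflow over the window equals the trial
fraction under competing exits; with no competing exits this is
`1 − (1−f)^(1/W)`). `immediate` is the default: calibration against
the published discounted totals favours it (uniform allocation leaves
the gene-therapy arm's discounted cost ~5% high and both headline
ICERs ~7% high; immediate brings every published total within ±4.3%).

### Dosing calendars and costs

Per-dose totals are the exact itemised sums: nusinersen
$110,000 + $2,576.50 administration = $112,576.50; AVXS-101
$3,054,344 + $114.98 = $3,054,458.98. AVXS-101 charges exactly one
undiscounted full-cohort dose at t = 0, which makes its ICER affine in
the acquisition price with slope 1/ΔQALY — the basis of the threshold
analysis. Nusinersen doses at months 0, 0.5, 1, 2, then every 4 months
from month 6 for life; each dose is weighted by the proportion of the
cohort in a dosed state at the dose time. Whether patients on
permanent ventilation keep receiving nusinersen is not stated in the
source material; calibration against the published nusinersen total is
decisive (dosing in PAV overshoots it by ~30%), so the default dosed
states are not-sitting, sitting and walking. This is configurable per
strategy.

State costs ($23,569 not-sitting / $9,896 sitting / $6,644 walking /
$27,693 PAV) are applied **per monthly cycle**. This is deliberate and
calibration-forced: an independent geometric-series oracle of the SOC
arm reproduces the published SOC total (~$923k) only under per-cycle
application; annual application would give ~$80k. Utilities (0.104 /
0.115 / 0.252 / 0.104; dead 0) are annual QALY weights, contributing
`u/12` per cycle lived.

### Calibration status and known reproduction limits

With the defaults above, all six published discounted totals are
reproduced within ±4.3% and the two headline ICERs within +3.9%
(AVXS-101 vs SOC) and +2.4% (vs nusinersen). The residual gap is
attributable to unpublished implementation details of the original
decision-modelling software (reward timing, transition ordering, the
exact life table); scans over half-cycle variants, discount timing and
transition ordering did not identify a combination that closes it.

The threshold price is the difference of two ~$1.1M-scale quantities
(`price* = WTP·ΔE − non-acquisition ΔC`), so base-case reproduction
error is amplified ~27-fold: at a WTP of $500,000/QALY a ±1% base-case
error moves the solved price by ~±$30k. Our reproduction places it
slightly below zero at that WTP (reported as "not cost-effective at
any non-negative price"), whereas the published analysis reports
~$80k; at WTP $1,000,000 both agree that the threshold price just
exceeds $1M, and the threshold curve is strictly increasing in WTP.
This sensitivity is a property of the quantity, not of the solver: the
closed form and an independent bisection agree to <$1.

## Survival-fitting pipeline

Published Kaplan-Meier figures are the only survival evidence for
several transitions, so the package includes the full
reconstruction-and-fit chain: step coordinates plus numbers-at-risk →
pseudo individual-patient data (the iterative interval-by-interval
censoring-allocation algorithm, with censor times spread uniformly
within risk-table intervals, event counts recovered from survival
drops with cumulative rounding, and input coordinates monotonised with
a warning when digitisation noise violates monotonicity) → maximum
likelihood fits of five families (exponential, Weibull, Gompertz,
log-normal, log-logistic) with right censoring → selection by AIC,
ties by BIC then parameter count → Cox-Snell residual diagnostics
(residuals `−log S(t_i)` should behave as unit-exponential censored
data). Optimisation is Nelder-Mead on log-transformed parameters
(Gompertz shape unconstrained), method-of-moments starting values,
function tolerance 1e-8; at least two events are required, otherwise a
fit is refused as non-identifiable. The actual digitised coordinates
behind the original curves are unpublished, so this machinery is
validated on synthetic fixtures (round-trip fidelity ±0.02 survival at
risk-table landmarks) and the published Weibull for sitting survival
is taken as given in the cohort model.

## Synthetic data

All pipeline inputs are generated:

* **Trial simulator** — exponential/Weibull event times with
  administrative censoring; presets mirror the pivotal-trial
  structures (80 + 41 subjects, 13-month follow-up; 12 subjects,
  24-month follow-up) with hazards matching the base-case monthly
  probabilities.
* **Published-figure emulator** — KM step coordinates with optional
  additive uniform digitisation noise (truncated to [0,1]) and
  numbers-at-risk at landmarks.
* **Life table** — Gompertz-Makeham annual hazard
  `q_x = 1 − exp(−(a + b·c^x))`, defaults a = 1e-4, b = 2.5e-5,
  c = 1.1, chosen so childhood mortality is negligible (q_0 ≈ 1.2e-4,
  cumulative mortality to age 20 < 1%) like a modern national life
  table. Because walkers face only this mortality and the 5% discount
  dominates late years, base-case results are insensitive to the
  stand-in (<0.5% of total QALYs).

Synthetic data share the structure but not the event times of the real
trials, so passing tests demonstrate correctness of the machinery, not
numerical agreement with the original reconstructed curves.

## Sensitivity analysis

* **One-way (tornado)**: every cost, utility, transition probability
  and Weibull parameter varied ±30% of its mean, all else fixed;
  utilities capped at 1 (clips recorded); output ordered by ICER
  range. The dominant drivers are the AVXS-101 price and the
  sitting/walking utilities, matching the published qualitative
  finding.
* **Probabilistic**: gamma for costs/prices and the (positive) Weibull
  parameters, beta for utilities and transition probabilities, as in
  the published input table. Utilities use mean/SD by method of
  moments; costs and probabilities have only min/max published, which
  are interpreted as a central 95% interval and fitted by
  mean-constrained least squares on the 2.5%/97.5% quantiles (a skewed
  distribution cannot match a symmetric interval exactly; the residual
  is a few percent at the lower quantile). The not-sitting and PAV
  utilities are identical by construction and sampled as one shared
  parameter (configurable). Each iteration applies one draw to all
  three strategies. Default 5,000 iterations; the seed is recorded in
  every output manifest and results are bitwise reproducible under it.
  The published acceptability probabilities depend on undisclosed
  distribution spreads; under this interpretation the probability that
  AVXS-101 is cost-effective vs SOC at WTP $1.75M is ≈0.36 (published:
  52.8%) and ≈0 at $50k (published: 1.2%).

## Problem sizes and runtimes

The deterministic pipeline (1200 cycles × 5 states × 3 strategies)
runs in milliseconds; the 5,000-iteration PSA in about 90 seconds on
one core. The analysis drivers write compact tables (annual trace
audit rows, a thinned CE-plane scatter, draw summaries); full
cycle-level and iteration-level streams are available through the
command-line interface.

## Known limitations

* The original model's cycle-reward and transition-ordering
  conventions are unpublished; reproduction accuracy is bounded at a
  few percent, and quantities that difference large totals (threshold
  price at low WTP) inherit that error amplified.
* No treatment discontinuation except death; no utility decrements for
  dosing procedures; no societal costs; no relapse from milestone
  states.
* The life table and all survival inputs beyond the published
  parameters are synthetic stand-ins.
* PSA distribution spreads for costs and probabilities are an
  interpretation of published min/max columns, not fitted to disclosed
  standard errors.
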