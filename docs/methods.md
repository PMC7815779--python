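# Methods

`microhealth` is a discrete-time, individual-level microsimulation of
health ageing in closed cohorts of Europeans aged 50+. Each simulated
person carries invariant demographics (birth year, sex, education,
country), five binary risk factors (current smoking, vigorous physical
activity, obesity, arterial hypertension, depression), a continuous health
metric HM ∈ [0, 100] summarising functional health, and a vital status.
The simulation advances in annual steps from a start year (default 2011)
to a horizon (default 2060); there are no new entrants, so cohort
replacement ("demographic metabolism") operates purely through differential
composition and mortality of the cohorts present at baseline.

## The yearly step

Each simulated year executes on the start-of-year snapshot, for every
alive individual:

1. **Survival.** Death occurs with probability
   `q' = expit(logit(q) + β_c)` where `q` is the baseline death
   probability for the individual's (age, sex, education, country,
   calendar year) and `β_c` a centred contrast effect for the category of
   start-of-year HM (see *Mortality* below).
2. **Risk factors.** Each factor F is redrawn as an independent Bernoulli
   trial with probability
   `logit P(F_t = 1) = β0 + β1(a−1) + β2 F_{t−1} + Σ_i β_i X_{i,t−1}`,
   an autoregressive distributed-lag (ARDL) logit model. Inside the
   simulator the gap is a = 1 year, so the duration term vanishes; it
   exists for estimation from panels with unequal wave gaps. The model
   gives a *net* probability — entry and exit flows are absorbed into one
   logistic equation, so `β0 + β2` at a = 1 is the probability of keeping
   a factor one already has (covariates at reference).
3. **Health.** With h = HM/100, the health metric updates
   deterministically on the logit scale:
   `logit(h_{t+1}) = logit(h_t) + Δ`,
   `Δ = β0 + β1 h + β2 h² + β3 h³ + Σ_i β_i X_{i,t}`.
   The cubic lets the decline rate depend on the current level (decline is
   faster from good health under the defaults); all stochasticity in a
   health trajectory enters through the risk factors and survival.
4. Age increases by one year. A dead individual is never touched again.

All three processes condition on the same pre-step snapshot (synchronous
update), so the ordering of operations inside a year is immaterial. The
composed exponential form sometimes written for the health update is
internally consistent only when read as the logit-scale composition above
(the update must invert the change model); that is the form implemented.

**Randomness.** Every stochastic draw comes from a counter-based (Philox)
substream keyed by (master seed, calendar year, process) and indexed by
individual id. Consequences: runs are exactly reproducible; row order
never affects results; scenarios run with the same master seed share all
uniforms — common random numbers (CRN) — so counterfactual contrasts are
paired and two runs of the same scenario have *identically zero* contrast;
and pinning a factor in a scenario skips only that factor's stream,
leaving every other draw untouched.

## Base population

The synthetic generator draws, in order: birth year (1920–1960; weights
emulate larger recent cohorts thinned by past mortality), sex (female
share rising with age), country (14 European countries, population-sized
weights), and education from a cohort-dependent composition in which the
low-education share falls logistically from ≈70% for pre-1930 cohorts to
<30% for the 1956–60 cohorts — the educational expansion that makes later
cohorts healthier at the same age. Risk factors are then imputed
*sequentially* (smoking → activity → obesity → hypertension → depression),
each from a logistic model on demographics and the factors already drawn —
a fixed-order analogue of chained-equation imputation, chosen because a
fixed visit order is deterministic and testable. Finally HM is imputed
from a linear model on logit(HM/100) with Gaussian noise (default SD 0.5
on the logit scale) and clamped to [ε, 100−ε], ε = 10⁻³ on the 0–100
scale, so the logit is always finite.

A user population can be loaded from CSV instead; rows violating the
structural invariants (HM outside [0, 100], birth year after 1960,
non-binary flags) are rejected with row-indexed diagnostics.

## Mortality

Baseline death probabilities come either from a long-format table
(age, sex, education, country, year, q) with constant extrapolation
beyond the tabulated range, or from a built-in Gompertz-type schedule —
logit(q) linear in age with additive sex/education/country shifts and a
negative calendar-year trend (improving longevity). The schedule is
explicitly illustrative: it produces realistic European 50+ levels
(q ≈ 0.01 at 65 for high-educated men, ≈ 0.07 at 85) but is not an
estimated life table.

The health gradient enters through a categorical transformation of HM
(default cutpoints 30 and 60: bad/medium/good, half-open bins, so HM = 60
is good). Raw category effects — estimable from panel data with the
mortality model in the estimation module — are re-centred before use so
that the whole population is the reference. Two centrings are provided:

* **arithmetic**: subtract the population-share-weighted mean of the raw
  effects; the weighted mean logit shift is then exactly zero;
* **death-calibrated** (used by the engine, once at baseline): solve for
  the single offset m with
  `Σ_i expit(logit(q_i) + raw_{c(i)} − m) = Σ_i q_i`.

The distinction matters because baseline risk correlates with health
category: the old are both frailer and likelier to die, and at small q the
logit shift acts multiplicatively (q' ≈ q·e^c), so arithmetic centring
preserves the mean logit shift but inflates expected deaths where c and q
are positively correlated. The death-calibrated offset preserves the
first-year expected death count exactly, which is the substantive
requirement: introducing the health gradient redistributes deaths toward
the unhealthy without changing the aggregate level the baseline schedule
encodes. Only the level is calibrated, and only once at baseline; in later
years the changing health composition is allowed to move aggregate
mortality, as it should.

The default good-health threshold of 60 reflects the observation that the
probability of dying rises markedly once HM falls below 60; the lower
cutpoint at 30 is a configurable choice giving the categorical effect at
least three levels.

## Scenarios

Nine built-in counterfactuals: Baseline; NoAH, NoObe, NoSmoke, NoDep
(each removes one factor); NoInactive (everyone does vigorous activity);
EqEdu (zeroes the low/medium-education coefficients in the health-change
model *only*, leaving education's effects on the transitions and on
baseline mortality intact); NoRisk (all of the above combined); and
BadHMAlive (the good-health mortality parameter applies to every HM
category, eliminating the mortality gradient by health). "Removing" a
factor sets it to zero at baseline *and* pins its transition to zero — a
prevalence removed only at baseline would be re-introduced by the
transitions within a few years. Other factors keep their coefficients, so
indirect pathways operate automatically (e.g. removing depression raises
physical activity, which slows health decline). Scenario outputs always
include the prevalence trajectories of all five factors so these indirect
effects stay visible. The scenarios are internal-consistency probes, not
policy forecasts.

## Outcomes

* **Average health**: unweighted mean HM over individuals alive at the
  start of each stratum-year (the synthetic population is self-weighting).
* **NYLP** (number of years lived per person): person-years over the
  outcome window (default 2015–2060) divided by the population alive at
  the start of the reference year (default 2015). Deaths contribute 0.5
  person-years in the year of death (mid-year convention).
* **NYLP in good health**: same denominator; only person-years whose
  start-of-year HM ≥ 60 count.

Strata with nobody alive are omitted rather than reported as NaN. The
overall NYLP decomposes exactly over strata weighted by initial stratum
shares; this identity is tested.

## Estimation

The three model families are fitted from stacked two-wave panel records
(one row per individual per wave pair, lagged state plus outcome) by
pooled maximum likelihood with cluster-robust (sandwich) standard errors
grouped by individual — the independence-working-correlation form of GEE,
whose point estimates coincide with the ordinary GLM/OLS fit. Binary fits
report percent concordance and the C-statistic (ties counted ½). Records
with HM at the bounds are ε-clamped with a warning; a duration term with
no variation (all gaps equal) is dropped with a flag rather than silently
estimated; rank-deficient polynomial terms are dropped and reported as
zero coefficients with a collinearity flag; binary covariates that
perfectly separate the outcome are rejected by name. Panel simulators
drawing records from known parameters support parameter-recovery testing
(all coefficients recovered within 3 robust SEs at n = 50,000, verified in
the acceptance suite) and the Mincer–Zarnowitz calibration regression
(observed on predicted; slope 1, intercept 0 under unbiasedness) closes
the loop on the population generator.

## Default parameters

Defaults live in `data/default_params.yaml`. Nine transition coefficients
(the education effects on obesity 0.692, depression 0.493, hypertension
0.313 and activity −0.244, and the lagged cross-effects smoker/obese/
depressed → activity −0.261/−0.333/−0.399 and smoker/obese/active →
depression 0.197/0.125/−0.234) reproduce published logit-scale estimates
from the European ageing-panel literature; the smoking model is purely
autoregressive (no education or cross-factor terms), matching the same
source. Everything else — intercepts, persistence terms, age splines
(piecewise-linear, knots at 50/60/75/90; hypertension incidence peaking
near 75, depression rising after 75), the health-change coefficients and
the Gompertz schedule — is illustrative: chosen once to give realistic
prevalences for a European 50+ population, a baseline population mean HM
near the mid-50s in 2015 declining to the low 20s by 2060, roughly 18–20
years lived per person over 2015–2060 of which 4–5 in good health, and
first-year mortality at life-table levels. All five risk-factor
coefficients in the health-change model are ≤ 0 (physical activity enters
as its complement, `inactive`), which is what gives the scenario suite its
dominance ordering. Users with panel data should re-estimate everything
via the estimation module; the `fit` CLI emits simulator-ready parameter
files.

## What the synthetic generator does and does not emulate

The generator reproduces marginal prevalences by age/sex/education, the
cohort education gradient, and the cross-factor correlation structure
implied by the sequential conditionals. It does not emulate survey
weights, household structure, migration, country-specific trends, or
measurement error in HM, and its residual noise on the logit of HM is
Gaussian by assumption. Passing tests therefore demonstrate the
*mechanics* — equations, stochastic machinery, scenario logic, estimation
consistency — under controlled conditions, not the empirical accuracy of
any particular published projection, which would require the original
estimated coefficient tables and external mortality schedules.

## Numerical choices and problem sizes

HM is clamped to [10⁻³, 100 − 10⁻³]; q = 0 and q = 1 are fixed points of
the mortality adjustment by continuity; the death-calibration offset is
found by bracketed root-finding (Brent, xtol 10⁻¹²) with an arithmetic
fallback when all baseline q are degenerate (0 or 1) and the offset can
have no effect. Half-open binning puts each cutpoint in the category
above it. The test suite uses populations of 2,000–100,000 and panels of
30,000–50,000; the scenario acceptance check runs the full nine-scenario
suite at n = 100,000 over 2011–2060, and the acceptance script defaults to
n = 50,000, sizes at which paired-MC noise on mean HM is a few hundredths
of a point in mid-projection years. The Monte-Carlo scaling check uses
96 replicates at n = 2,000 vs 8,000 (script: 48 at 1,000 vs 4,000), where
the √n law predicts an SD ratio of 2.

## Known limitations

Annual discrete time replaces continuous-time event scheduling; yearly
probabilities are the native quantities of all three models, but
within-year competing risks are not modelled (death simply precedes the
updates). Education and country are invariant; there is no entry cohort
after baseline, so results beyond ~2055 describe a small, very old
surviving population. The contrast centring is done once at baseline;
annual re-centring would hold aggregate mortality to the baseline
schedule permanently, which would defeat the purpose of modelling a
health-driven mortality feedback.
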