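# Methods

This note documents the model implemented in `foodscba`: a social
cost-benefit analysis (SCBA) of consumer-price interventions on food —
a 15% or 30% price increase on total meat (red, processed, poultry) and a
10% price decrease on fruit & vegetables (F&V) — against a no-policy
reference, over a 30-year horizon (2018–2048) on a Dutch-scale population.

## Synthetic inputs

The original analysis rests on four data sources that are not publicly
distributable: national food-consumption survey microdata, national
demography and disease registries, commercial life-cycle-assessment (LCA)
footprints, and market price data.  `foodscba.synthetic` generates seeded
stand-ins with the same statistical structure.  Everything derives from one
integer seed and a `GenerationConfig`; the same pair reproduces the bundle
bit for bit, and all tables serialize losslessly to CSV/JSON
(`write_bundle` / `read_bundle`).  `AnalysisConfig` round-trips through a
versioned YAML schema (`config_to_yaml` / `config_from_yaml`).

**Demography.** Ages 0–100 in single years (100+ closed and pooled), two
sexes.  Background mortality is Gompertz–Makeham
(`m = c + a_sex·exp(b·age)`); the all-cause schedule adds baseline
prevalence-weighted disease excess mortality.  The base pyramid is the
*stationary* age distribution of that schedule, normalized to
16,979,107 persons — the population implied by a national meat consumption
of 665,581,000 kg/yr at 39.2 kg/person/yr — with a constant newborn inflow.
Because the demographic projection uses the same schedule, the reference
age structure (and hence the reference population-mean intake) is constant
over the horizon by construction.  This is a deliberate idealization of the
"no autonomous trend" reference: real populations age, but a stationary
reference isolates the policy effect from demographic drift and makes the
reference identity exactly testable.

**Consumption.** Mean intake per (age, sex) cell uses smooth hump-shaped
age profiles with a sex gradient and mild seeded lognormal cell noise, then
is calibrated exactly so the population-weighted means hit 107 g/day total
meat (split 45/30/25% red/processed/poultry) and 250 g/day F&V.  Within a
cell, intake is gamma distributed with configurable shape (default 4;
variance = mean²/shape) — non-negative and right-skewed, as intake data
are.  Day-to-day variance and seasonality are not modelled.

**Epidemiology.** Five chronic diseases: diabetes type 2, stroke, lung
cancer, coronary heart disease (CHD), colorectal cancer.  Incidence and
prevalence are logistic-in-age curves with sex factors; excess mortality
and disability weights are per-disease constants.  Relative risks (RRs)
attach to two exposures — red+processed meat (poultry carries no health
risk) and F&V — over three intake categories each (boundaries 50/100 and
150/250 g/day), with 95% CIs and RR ≡ 1 in the reference category.  The
magnitudes (meat: up to 1.42 for diabetes; F&V protective: down to 0.70 for
stroke) are *placeholders of plausible size*: the underlying review's
values are unpublished, so they are configuration, not constants.  They are
calibrated so the qualitative pattern of the study conditions holds —
a meat tax averts most diabetes cases, the F&V subsidy most stroke cases,
and CHD (no direct meat association by default) shows the compensatory
increase discussed below.

## Consumption projection

Quantity response to a price change Δp uses the own-price elasticity ε
(meat −0.60, 95% CI −0.66..−0.54; F&V −0.53, CI −0.59..−0.48).  Default
form is iso-elastic, `q1 = q0·(1+Δp)^ε`; a `linear` form
`q1 = q0·(1+ε·Δp)` is available.  The two bracket the published endpoint
for the 15% tax (98.39 vs 97.37 g/day around the published 98.2); the
iso-elastic default is retained everywhere and the residual gap (published
endpoints embed category effects of the original micro-engine that no
closed demand form reproduces) is accepted and documented rather than
calibrated away.  Policy pass-through is full in the first year after the
base year and constant thereafter; cross-price substitution is out of
scope.  Because the elasticity is uniform across cells, the national
relative change equals the cell-level change exactly.

## Health impact model

A proportion-based (macro) multistate model rather than an individual
microsimulation: each (age, sex) cell carries a population count and a
prevalence proportion per disease.  This is deterministic, fast, and
equivalent in expectation for cell-level rates; what it gives up is
individual risk-factor history and stochastic small-sample noise.  Monte
Carlo therefore covers *parameter* (RR) uncertainty only.

Annual cycle:

1. **Categories.** Cell intake category proportions are gamma CDF
   increments over the category intervals (point mass in the degenerate
   zero-dispersion limit).
2. **Incidence scaling.** Scenario incidence is baseline incidence times
   `Σ p'_c RR_c / Σ p_c RR_c` (scenario vs reference category proportions)
   per exposure, multiplied across exposures — a potential-impact-fraction
   style rescaling.  With p' = p or RR ≡ 1 the factor is exactly 1, so an
   exposure with unit RRs (poultry) is inert.
3. **Mortality.** All-cause cell rate = background + Σ prevalence·excess;
   rates convert to probabilities as `1 − exp(−rate)`.  Within a disease,
   prevalent cases die at the others' average rate plus their own excess
   (additive on the rate scale); diseases are treated as independent.
4. **Aging.** Survivors shift one age; 100+ pools; newborns enter at age 0
   with the baseline age-0 prevalence.  Population conservation
   (`alive_{t+1} = alive_t − deaths + newborns`) holds exactly.
5. **QALYs.** Cell utility = `1 − Σ prevalence·disability weight`
   (additive comorbidity decrement, floored at 0); QALYs are
   population-weighted utility, so they include both morbidity and the
   life-years of survival differences.  The ledger uses this total.

**Compensatory dynamics.** Averting a fatal disease lengthens survival, so
an unassociated disease's absolute case count can rise under an effective
policy.  With the default calibration the meat tax produces exactly this
CHD pattern; it emerges from mortality feedback, not from any hard-coded
rule.

**Monte Carlo.** Each of 100 iterations (default) redraws every
non-reference RR from a normal with sd = (CI width)/3.92, truncated below
at 10⁻⁶, and reruns the scenario (the reference state is RR-invariant).
Reported bounds are the 2.5th/97.5th percentiles across iterations (the
alternative min–max reading of "the 95% CI of 100 simulations" was
rejected as less standard).  Degenerate zero-width CIs are allowed and
collapse the bounds onto the point run.  Everything is reproducible from
the seed.

`estimate_transitions` exposes the net annual flows between adjacent intake
categories implied by two successive category distributions (the
cumulative-difference solution, which is the minimal adjacent-flow
transport and conserves mass).  The macro engine consumes category
proportions directly, so this operation serves diagnostic and
interoperability purposes.

## Environmental accounting

Five LCA indicators per kg of food: GHG (kg CO₂-eq), acidification
(kg SO₂-eq), fresh-water eutrophication (kg P-eq), salt-water
eutrophication (kg N-eq), land use (m²a).  Synthetic footprints make every
meat group strictly dominate F&V per kg (a structural assumption of the
analysis, enforced by validation).  Production-efficiency gains reduce all
footprints linearly in percentage points of base-year intensity — 1.25%/yr
in the main analysis (the annualization of a 20% decline over 16 years),
0.75%/yr and 1.75%/yr in the low/high variants; "linear" is read as
arithmetic, not compounded, because 20%/16 = 1.25% is exactly the stated
annualization.  Since the same factor multiplies scenario and reference,
relative scenario-vs-reference changes are efficiency-invariant and
identical across indicators (both are tested identities).  Monetization is
the dot product with unit damage costs (0.057, 5.40, 3.11, 1.90,
0.0261 €/unit), scaled by ×2/×0.5 in the high/low cost variants (the exact
variant magnitudes are unpublished, so the factors are configuration).

## Monetization and ledger

All flows are nominal euros per year, discounted at 3%/yr (1.5%/4%
variants) to 2018 and reported in million €.

* **Consumer surplus**: rule of half.  Default is the standard
  `½·Δp·(q0+q1)`; the triangle form `½·Δp·Δq` is available as
  `as_printed` because some guideline texts print it that way.  The full
  form is the default since only it produces consumer-surplus magnitudes of
  the order the 30-year ledgers require; the discrepancy between the two is
  surfaced as an explicit option, not silently resolved.
* **Policy revenue** (government): `Δp·p_t·q1 − VAT·p_t·(q0−q1)` per priced
  group, with food VAT 6% and prices following a 1.7%/yr CPI trend; one
  formula covers taxes (positive) and subsidies (negative).
* **Healthcare** (government): averted prevalent cases × per-disease cost
  per case-year (synthetic magnitudes; the national cost-of-illness tables
  are unpublished).  Sign flips for diseases whose cases rise.
* **Health outcomes** (consumers): QALY gain × €50,000 (main) and €100,000
  (variant; totals are reported for both).  Omitted entirely under the
  perfect-information assumption.
* **Productivity**: averted working-age (15 ≤ age < 75) cases ×
  (absenteeism+presenteeism cost + participation fiscal effect).  The
  friction-cost method keeps a configured fraction (default 0.2) of the
  participation stream; fraction 1 reproduces the human-capital value
  exactly.  A consumer share (default 0.13) splits the stream between
  stakeholders; the split is configuration because the published
  stakeholder table implies but does not state it.
* **Policy costs** (government): a one-off €20M implementation cost booked
  undiscounted in the base year, so the ledger prints −20 exactly.

Stakeholder mapping: consumers carry consumer surplus, QALYs and their
productivity share; government carries revenue, environment, healthcare,
policy costs and the remaining productivity.  Societal total = Σ effects =
Σ stakeholder totals (machine-precision accounting identity).  Monte-Carlo
bounds attach only to the RR-dependent rows, propagated by monetizing each
iteration's delta stream and taking percentiles of the discounted totals.

## Sensitivity analysis

`run_sensitivity` reruns the whole pipeline per one-way variant:
elasticity CI bounds, discount 1.5%/4%, HEC-LEG / LEC-HEG environment
settings, friction vs human capital, perfect information, QALY €100k.  A
variant at the base setting reproduces the base ledger bit for bit (same
seed, same code path).  The output is a tornado-style table of societal
totals with bounds.

## Numerical choices and problem sizes

* 1-year cycles, 31 annual states (2018–2048); grid 101 ages × 2 sexes.
* Rate→probability: `p = 1 − exp(−rate)` throughout.
* Default runs use 100 Monte-Carlo iterations (seconds on one CPU); tests
  use 2–40 iterations and 5–10-year horizons where the property under test
  does not need the full design.
* Gamma category proportions fall back to a point mass at zero for
  zero-mean cells; prevalence updates guard empty cells; prevalence is
  clipped to [0,1].
* All randomness flows through `numpy.random.default_rng(seed)`.

## What passing tests do and do not show

The synthetic bundle emulates the *structure* of the study inputs, with
exact calibration to the published consumption baselines and population
scale.  Consumption and environment endpoints are therefore
desk-reproducible and checked numerically.  Euro totals are not: they
depend on unpublished survey microdata, RR values, cost-of-illness and
price tables, so the ledgers are validated at the level of sign patterns
(consumers net payers under a tax, government under a subsidy; positive
societal totals under the shipped calibration), accounting identities and
sensitivity-direction monotonicity — matching magnitudes would certify
nothing about real data.  Known limitations: no cross-price substitution,
no SES stratification, no combined tax+subsidy scenario, no trade/leakage
effects, stationary demography, independent diseases, and placeholder RR
and unit-cost magnitudes.
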