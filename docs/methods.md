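# Methods

This note documents the model implemented by `her2cua`: its structure,
conventions, parameterisation, the design choices made where more than one
reasonable convention exists, and what the synthetic-data tests do and do
not demonstrate.

## Cohort model

A closed cohort of women with early/locally advanced HER2-positive breast
cancer enters the model at age 50, entirely in the event-free state, and is
propagated in 1-month cycles to age 100 (600 cycles). The five states are
event free (EF), locoregional recurrence (LRR), metastasis (MET), remission
(REM) and death (absorbing). Structural assumptions: chemotherapy backbones
are outcome-neutral across arms; a patient experiences at most one
locoregional recurrence (a second one is treated as metastatic disease);
patients in remission face general-population mortality; death collects both
cancer and background deaths.

The transition matrix is time-inhomogeneous through two channels: the
EF→event probability *q(t)* follows each strategy's piecewise baseline
schedule composed with its efficacy hazard ratio, and background mortality
*m(age)* follows an eight-band national life table (monthly probabilities
0.00027 at 50–54 up to 0.00708 at 80+; ages ≥ 85 reuse the last band). In
the EF and REM rows background mortality competes additively with the
disease transitions and the stay probability absorbs the remainder; the
engine raises an error if exits ever exceed 1. Events from EF split 25/75
between LRR and MET, the split applied after hazard-ratio scaling (the
efficacy evidence concerns event-free survival, i.e. the combined event
hazard). The LRR row's printed exit probabilities sum to exactly 1
(0.02317 + 0.01064 + 0.96619), so in the base case LRR is a one-cycle tunnel
state; the "LRR year 2 onwards" cost piece is implemented (time-in-state
clock) but unreachable at base-case values.

### Months-in-state bookkeeping

Costs for LRR and REM depend on time in state, so the trace resolves
occupancy by (state, months-in-state) with tenure capped at 121 months (all
months beyond 120 share the "after 10 years" cost piece; the cap bounds the
tunnel dimension without affecting any payable quantity). A cohort fraction
entering a state carries tenure 0 during its first cycle there; stayers age
one bucket per cycle. EF tenure coincides with model time because nothing
re-enters EF.

### Efficacy composition

The published inputs give (a) per-strategy baseline EF→event schedules —
one shared 0.01015/month rate for the strategies with single-agent adjuvant
trastuzumab, trial-derived year-by-year rates for the dual-adjuvant
strategies (S4: 0.00118/0.00229/0.00220/0.00220 over years 1–5; S5:
0.00798), and 0.01015 for everyone after month 60 — and (b) hazard ratios
versus the comparator (0.54 for pertuzumab arms, 0.85 for lapatinib arms),
with the treatment effect capped at 12 years. How (a) and (b) compose is
not stated, so the package exposes three modes:

- `HR_ON_BASELINE` (default): the hazard ratio rescales the strategy's own
  baseline probability, `p' = 1 − (1 − p)^HR`, for every cycle before month
  144; afterwards the raw post-60-month baseline applies.
- `TRIAL_THEN_HR`: the trial-derived schedules are used unscaled for their
  first 60 months, with the hazard ratio applied only from month 60 to 144.
- `BASELINE_ONLY`: hazard ratios ignored (diagnostic).

The default was chosen by calibration against the published deterministic
results: it reproduces all five strategies' discounted LY/QALY to within
1.4% and the full incremental table (including the S4/S5 dual-adjuvant
strategies) to within the acceptance tolerances, whereas `TRIAL_THEN_HR`
underestimates the dual-adjuvant strategies' survival by 2–3% and distorts
the sequential ICER between S2 and S5 by over 20%.

### Valuation conventions

Occupancy, utilities and costs are valued at cycle start with no half-cycle
correction; a cohort fraction dying within a cycle accrues nothing for that
cycle. With monthly cycles the half-cycle bias is small (≈0.1% of
discounted LY); cycle-start valuation was retained after comparing
cycle-start, cycle-end and half-cycle variants against the published
tables. Discounting multiplies cycle-*t* amounts by `(1 + r)^(−t/12)` with
r = 3%/year for both costs and outcomes (held as two fields so the one-way
DSA can vary them separately); cycle-0 amounts, including the one-time
neoadjuvant outlay, are undiscounted. EF utility follows the model clock
(0.81 in the first model year, 0.85 after); LRR/REM/MET use flat weights
(0.72/0.82/0.70). EF costs follow the model clock, LRR and REM costs their
time-in-state clocks, MET a flat monthly rate. All cost rows labelled by
year denote the monthly amount applying during that period — this monthly
reading, not an annual-lump reading, reproduces the published lifetime
costs. The public perspective counts direct medical costs; the societal
perspective adds direct non-medical costs. Neoadjuvant treatment is charged
as a one-time lump (DMC, plus DNMC under the societal view) at cycle 0.

## Parameterisation and configuration

All inputs live in a flat registry of named scalars (e.g.
`tp.lrr_to_met`, `cost.neoadj_dmc.s2`, `util.metastasis`,
`mort.age_70_74`, `hr.s3`) from which the structured objects — strategy
specs, cost schedules, life table — are assembled and validated. Each
uncertain value carries a sampling distribution: Beta for probabilities,
shares and utilities, Gamma for costs, LogNormal for hazard ratios. Beta and
Gamma are built by method of moments from (mean, SE); most SEs are 10% of
the mean, with the printed SEs (utilities, life-table bands, trial
transition probabilities) taking precedence. LogNormal uses
`mu = ln(point)` and `sigma = (ln hi − ln lo) / (2 × 1.959964)` from the
published 95% CI.

Configurations serialize to JSON or YAML (values + distributions +
settings); the life table and cost schedules may be supplied as CSV files
whose rows are mapped onto the canonical band/piece boundaries, with
validation errors naming the offending row. Loading a serialized set
reproduces the original exactly. Every report written by the CLI embeds a
SHA-256 hash of the resolved configuration.

Validation distinguishes structural invariants (ranges, contiguity, simplex
bounds, absorbing death, zero dead-state cost) from plausibility checks;
the only plausibility check, life-table age-monotonicity, is enforced for
loaded and builtin sets but not for sampled or perturbed ones, because the
two oldest published bands are equal and independent draws legitimately
invert them about half the time.

## Uncertainty analyses

**PSA.** Each of *n* iterations (default 1,000) draws every uncertain
parameter independently — Table-level rows that feed several schedule
pieces are drawn once and shared — rebuilds the parameter set, and reruns
the cohort model for all five strategies. The LRR/MET event split is
sampled as a single Beta on the LRR share with the MET share as complement.
The three LRR exit probabilities are drawn independently and rescaled onto
the simplex only when their sum exceeds 1; the renormalisation count is
reported on the result. Randomness uses one root seed with per-iteration
`SeedSequence([seed, i])` substreams and sorted-name draw order, so results
are exactly reproducible and iterations are independent. CEACs report, per
willingness-to-pay value, the fraction of draws in which each strategy has
the highest net monetary benefit (`QALY × WTP − cost`), ties split equally;
the CE plane reports per-draw incremental (cost, QALY) pairs against the
comparator with quadrant counts.

**One-way DSA.** Each parameter in turn is set to the 2.5th/97.5th
percentile of its sampling distribution (hazard ratios: the printed CI
bounds; a ±20% convention is also available), the model is rerun for both
strategies in the comparison, and the signed ICER is recorded. Discount
rates use 0%–6% bounds, a common convention where the source is silent.
Raising a single LRR exit above the simplex triggers the same
renormalisation as the PSA. Dominance reversals (e.g. the lapatinib hazard
ratio at its upper bound 1.22, where the intervention loses QALYs) are
flagged categorically alongside the signed value, never dropped. The
tornado table sorts by ICER range and keeps the top 10 by default.

**Threshold (price-reduction) analysis.** The named cost components of one
strategy are scaled by (1 − r) and its ICER against the reference is
recomputed over r ∈ {0%, 5%, …, 100%} (a bisection mode refines to 0.1%).
The `NEOADJUVANT` component is the strategy's own one-time neoadjuvant-phase
outlay *under the active perspective* — direct medical cost alone for the
public payer, plus the phase's non-medical lump under the societal view.
This perspective-consistent reading is a deliberate choice: the source does
not define the component, and the base-case margin sits within half a grid
step of the 25% grid point, so the narrower medical-cost-only reading lands
one step higher. The `ADJUVANT_EF_YEAR1` component scales the strategy's
adjuvant-year monthly DMC excess over the single-HER2 adjuvant backbone
(strategy 2's), which isolates the continued dual-agent cost.

## Budget impact

Public perspective, undiscounted (standard budget-impact practice). The
year-1 treated population is (13,647 five-year-prevalent + 4,447 incident)
× 66% early stage × 22% HER2-positive × coverage (20% or 60%); years 2–5
treat the incident cohort only. Fractional patient counts are retained.
Each cohort contributes the strategy's undiscounted per-cycle public cost
stream from the cohort engine, aligned to its start year; a fiscal year's
budget sums the active cohorts' twelve-month slices, so later years combine
the new cohort's treatment phase with earlier cohorts' continuing state
costs. Incremental budgets and budget ratios are reported against the
comparator; ratios are coverage-invariant by construction. Year-1 figures
reproduce the published values to well under 1%; the year-2-to-5
attribution rule behind the published table is not fully specified, and
this implementation's straightforward cohort accounting lands within a few
percent of those rows.

## Synthetic models and the microsimulation oracle

`random_model(seed, n_states)` generates valid parameter sets of the same
shape as the packaged model — random piecewise event schedules, monotone
life tables, Dirichlet LRR exit rows, random utilities/costs/hazard ratios
with matching sampling distributions, and random horizons — deterministic
in the seed. Reduced state counts switch pathways off (4 states: no
remission; 3: no locoregional pathway; 2: background mortality only), which
exposes closed-form survival benchmarks (pure survival-product and
geometric-series life expectancy) that the engine must match to 1e-12.

`microsim_oracle` simulates individual monthly trajectories using the same
transition rows, clocks and valuation conventions as the cohort engine, so
the two computations share no propagation code yet must agree in
expectation; tests require agreement within three Monte Carlo standard
errors on LY, QALYs and costs for the base case (200,000 patients) and for
twenty seeded synthetic models (20,000 patients each). These checks verify
internal consistency and the implementation of the stated model — they do
not, and cannot, validate the model's clinical realism, the efficacy
inputs, or transportability beyond the parameterised setting.

## Problem sizes and numerical notes

Deterministic runs use the full 600-cycle horizon and are exact to
floating-point accumulation (mass conservation is asserted to 1e-10 per
cycle, transition rows to 1e-12). The PSA default of 1,000 iterations
matches the published analysis (binomial SE ≈ 1.6 percentage points on a
55% CEAC probability); the test suite uses smaller draws (60) for
distributional sanity checks and the full 1,000 for the acceptability-curve
reproduction. Ties in CEAC winners are split equally; an ICER with zero
QALY difference is reported as undefined rather than ±infinity; dominance
sign patterns raise typed errors in `icer` and are flagged (not suppressed)
in tables.

## Known limitations

- The efficacy composition rule and the threshold component definition are
  calibrated choices among readings the source leaves open; alternatives
  are implemented and selectable, and the headline figures shift by a few
  percent across them.
- The "LRR year 2+" cost piece is inert under base-case transition values.
- No individual-level heterogeneity, adverse-event states, market-share
  dynamics or price-inflation projection; hazard ratios and utilities are
  consumed as published, not re-derived from trial data.
- Budget-impact years 2–5 reproduce the published pattern approximately,
  not exactly (attribution rule under-specified in the source).
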