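# Methods

## Model structure

`remarkov` implements a three-state Markov cohort model for adults with
obesity and type 2 diabetes mellitus (T2DM) comparing sleeve gastrectomy
(SG) against pharmacological therapy (PT, oral glucose-lowering agents).
The states are **T2DM** (on glucose-lowering treatment), **remission**
(normal glycaemic control off glucose-lowering drugs, symptomatic
treatment continuing at reduced intensity) and **death** (absorbing).
Every cohort member enters in T2DM at age 40; cycles are annual; the
horizon is 60 cycles, so the maximum attained age is 99 — effectively a
lifetime horizon under the assumption that nobody outlives 100.

Within each cycle the transition row for a live state is composed
**death-first**: the background annual death probability `qx` for the
attained age (start age + cycle − 1) is multiplied by a state-specific
hazard-ratio multiplier (capped so the product stays ≤ 1) and applied
first; the surviving mass then splits between staying and moving by the
remission-entry probability (from T2DM) or the relapse probability (from
remission). This ordering keeps each row an exact probability
distribution with no renormalisation. An optional perioperative death
probability for surgical strategies composes with background mortality in
cycle 1 only (default 0).

Remission entry is blocked during a **two-cycle treatment lockout**:
remission can first be occupied in the trace row after cycle 3, i.e.
after two full years of treatment, for both strategies. Rewards for
cycle *t* are paid on the occupancy *after* the cycle-*t* transition, so
a member must survive a cycle to accrue its annual cost and utility, and
remission utility is first earned in year 3.

## Economic evaluation

Annual costs are direct medical costs only, stored at component level
(consultation, tests, drugs by class, test strips, the operation fee, …)
in 2023 US$ at the fixed rate 28.0153 TRY/US$, for two payer
perspectives: the Social Security Institution tariff (SUT) and the Public
Health Service Price Schedule (PHSP). Costs vary by strategy, state and
**cycle band** (PT: years 1–2 vs year 3+; SG: year 1 vs year 2+),
mirroring the source tables. Band totals are always recomputed by
summation; the totals printed in the source are carried only as
annotations because several are inconsistent with their own components
(differences of roughly one test-strip cost, plus one text-vs-table
conflict). `validate_cost_tables` reports all of these without failing a
run — the component amounts are treated as the primary data.

Utilities are 0.772/year in T2DM (pooled literature estimate), 0.812 in
remission (general-population estimate) and 0 when dead. QALYs and costs
are both discounted at 3%/year (5% in the scenario analysis). The default
discount convention is *first-cycle-undiscounted*, factor
`(1+r)^−(t−1)` for cycle *t*; an *end-of-cycle* convention
(`(1+r)^−t`) is available behind one config switch, as is an optional
half-cycle correction that halves the first and last cycle weights. The
source does not state which conventions its software used, so both are
implemented and the default is stated here.

Strategies are compared by incremental cost-effectiveness ratio
(ICER = ΔC/ΔE, undefined when ΔE = 0), net monetary benefit
(NMB(λ) = λ·E − C) and a dominance label read off the signs of (ΔC, ΔE).
Default willingness-to-pay anchors are 10,994 and 39,330 US$/QALY (the
1× and 3× GDP-per-capita figures quoted by the source; note these two
are not internally consistent — 3 × 10,994 ≠ 39,330 — so both are kept
verbatim as defaults, and `threshold_defaults(gdp)` builds a clean
(1×, 3×) pair from any GDP figure). All internal arithmetic is full
precision; rounding happens only in reports (costs/QALYs to 2 decimals,
headline ICER to the nearest integer).

## Transition inputs and calibration

The strategy transition probabilities behind the published results were
never printed. The bundled base case ships *illustrative* values
(PT: remission 0.05/yr, relapse 0.10/yr; SG: remission 0.35/yr, relapse
0.04/yr; excess T2DM mortality hazard ratio 1.5 with remission at
background mortality) intended to be replaced via the config file or by
calibration.

The calibration stage fits chosen free parameters to lifetime discounted
cost/QALY targets by minimising the weighted squared **relative** error,
which is scale-free across US$ and QALY targets. The optimiser is a
coarse grid scan (points per dimension shrunk to cap total evaluations)
seeding Nelder–Mead simplex refinement with bounds enforced by
clamp-plus-penalty, followed by a bounded trust-region least-squares
polish of the residual vector for the final digits. Everything is
deterministic. On synthetic ground truth, fitting (remission, relapse)
per strategy to that strategy's noiseless lifetime cost and QALY recovers
both probabilities to ~1e-13 (the test tolerance is 1e-3).

Identifiability caveat: when both live states carry identical mortality,
lifetime discounted cost and QALY depend on the two probabilities only
through discounted remission-time, and the pair is not identifiable from
those two targets. The synthetic ground-truth generator therefore draws
an excess T2DM mortality hazard ratio in [1.3, 2.0] (remission at
background) — clinically reasonable for uncontrolled T2DM with obesity —
which makes the (cost, QALY) map locally injective.

`scripts/acceptance.py` also runs a calibration *demonstration* against
the published lifetime totals. The published cost totals are not jointly
reachable under the bundled cost schedules (the schedules themselves
bound the achievable annual spend below what the published lifetime costs
imply), and using them as targets collapses the fit into a degenerate
corner with ΔE = 0. The demonstration therefore calibrates the
effectiveness surface exactly — a shared excess-mortality multiplier on
T2DM from the comparator QALY (wide box [1, 25], because this parameter
also absorbs the level gap between the synthetic life table and the
unpublished national one), then the surgical remission-entry probability
from the intervention QALY — and reports the four cost totals as
out-of-sample predictions with their relative residuals (about −20% to
−33%). Residuals are genuine model output; nothing is assumed zero.

## Sensitivity analysis

**One-way (tornado).** Each parameter is re-run at its low and high end
with everything else at base; entries are sorted by outcome width
(descending, ties broken lexicographically by parameter path). Default
ranges: ±20% for costs and utilities (utilities clamped to [0, 1]), ±20%
relative for probabilities (clamped), discount rate swept 0–5%. Default
metric: incremental NMB at the 3×GDP threshold. A range end that
produces an invalid bundle is flagged on its entry and the sweep
continues. Best-/worst-case scenarios apply every
intervention-favourable (resp. unfavourable) range end simultaneously,
with favourability read off the one-way sweep.

**Probabilistic.** Uncertain parameters get method-of-moments
distributions: Beta for [0, 1] quantities (`α = m·ν`, `β = (1−m)·ν`,
`ν = m(1−m)/se² − 1`), Gamma for non-negative costs
(`shape = m²/se²`, `scale = se²/m`); zero-valued quantities are held
fixed. Standard errors were not published; the default is se = 10% of
the mean, overridable per parameter. Draws are independent (no
correlation structure was published). Each of the default 1,000
iterations resamples every parameter, rebuilds the bundle, runs both
strategies and records (ΔC, ΔE); an invalid draw is resampled and
counted. The per-draw child seed is
`SeedSequence([master_seed, draw_index, attempt])`, so any single draw is
independently reproducible. The CEAC reports, per threshold λ, the
fraction of draws with λ·ΔE − ΔC > 0. The published "1,000 iterations
and 500 samples" is interpreted as 1,000 second-order parameter draws
with an optional 500-trial first-order microsimulation layer; the
first-order layer is off by default because the cohort expectation is
exact given parameters (the microsimulation engine exists and is checked
against the cohort trace at 3 Monte-Carlo standard errors, n = 10,000).

## Synthetic data

The life table is a Gompertz–Makeham stand-in for the (non-redistributed)
national annual life table: hazard(age) = 0.0005 + 2e-5·exp(0.1·age),
`qx = 1 − exp(−hazard)`, ages 40–99. The exponential form keeps qx in
[0, 1] by construction and monotone in age. The defaults put remaining
life expectancy at 40 in the high-30s to mid-40s with the modal age at
death in the mid-80s — realistic for a middle-income general population,
though deliberately not fitted to any particular national table. Ground
truth bundles draw remission entry high for SG (0.25–0.60) and low for
PT (0.05–0.20), relapse 0–0.15, and jittered life-table parameters, and
always pass bundle validation; hidden truth records are stored beside,
never inside, the bundle so recovery tests cannot leak.

What the synthetic inputs do **not** emulate: complication sub-states
(micro-/macro-vascular disease), surgical re-operations, BMI
trajectories, cohort heterogeneity in age/sex, or correlated parameter
uncertainty. Passing tests therefore demonstrate the correctness of the
engine, the economics and the calibration machinery under the stated
model structure — not the clinical accuracy of any particular transition
estimate for the Turkish population.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 100 random bundles for the
engine property checks, 10,000 individuals × 5 bundles for the
microsimulation/cohort agreement (3σ bands), 20 bundles × 2 strategies
for calibration recovery (tolerance 1e-3 absolute), and 1,000 PSA
iterations. Trace rows are required to sum to 1 within 1e-12; band totals
are exact sums; moment fits round-trip mean and variance within 1e-9.
Ties, degenerate inputs: zero-QALY differences leave the ICER undefined
rather than ±inf; hazard-ratio products are capped at probability 1;
equal tornado widths sort by parameter path; a calibration objective that
is non-finite at every grid point raises a calibration failure with
diagnostics rather than returning a point.
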