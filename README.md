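# remarkov

A Markov cohort cost-utility model of type 2 diabetes (T2DM) remission,
comparing **sleeve gastrectomy (SG)** against **pharmacological therapy
(PT)** for adults with obesity and T2DM, priced under two Turkish payer
perspectives (the Social Security Institution tariff, SUT, and the Public
Health Service Price Schedule, PHSP).

It is written for health-economics analysts who want the full pipeline as
tested, scriptable code rather than a spreadsheet or a proprietary model
file: parameter loading and validation, the cohort engine (plus an
individual-level microsimulation of the same process), discounted
cost/QALY accrual, ICER/NMB decision metrics, one-way and probabilistic
sensitivity analysis, and a calibration stage that recovers unpublished
transition probabilities from lifetime targets.

## The model

Three health states — T2DM, remission, death (absorbing) — with annual
cycles over a 60-year horizon from age 40. Everyone starts in T2DM;
remission (normal glycaemic control off glucose-lowering drugs) is
reachable only after a two-year treatment lockout. For a live state the
cycle-*t* transition row is composed death-first:

```
q      = min(qx(age) · HR_state, 1)            age = start_age + t − 1
T2DM:      (1−q)(1−p_rem),  (1−q)·p_rem,  q    (p_rem = 0 while t ≤ lockout)
REMISSION: (1−q)·p_rel,     (1−q)(1−p_rel), q
```

Discounted totals per strategy are
`C = Σ_t d_t Σ_s occ(t,s)·c_s(t)` and `E = Σ_t d_t Σ_s occ(t,s)·u_s`
with `d_t = (1+r)^−(t−1)`, r = 3%. Strategies are compared by
`ICER = ΔC/ΔE` and `NMB(λ) = λ·E − C` at willingness-to-pay thresholds
anchored to 1× and 3× GDP per capita.

Annual costs are stored at component level (consultation, tests, drug
classes, test strips, the operation fee, …) in 2023 US$ (28.0153
TRY/US$), by strategy × perspective × state × cycle band. Utilities are
0.772 (T2DM), 0.812 (remission), 0 (dead). The transition probabilities
were not published; the package ships illustrative defaults and a
calibration stage to replace them.

## Worked example

```python
from remarkov import CostUtilityModel

model = CostUtilityModel.base_case("SUT")   # bundled published inputs
res = model.run()
print(res.summary())
```

```
Cost-utility analysis — perspective SUT, SG vs PT
========================================================================
strategy total_cost incremental_cost total_qalys incremental_qalys cost_per_qaly    icer
      PT   3,505.56                        17.08                          205.27
      SG   2,930.38          -575.18       18.16              1.08        161.36 -530.90
------------------------------------------------------------------------
ICER: -531 US$/QALY   dominance: intervention dominant
incremental NMB at WTP     10,994:      12,486.03 US$  (cost-effective)
incremental NMB at WTP     39,330:      43,185.14 US$  (cost-effective)
(per-patient values; cohort of 1,000 scales report aggregates only)
```

Under the bundled *illustrative* transition defaults (SG remission 0.35/yr
vs PT 0.05/yr), surgery ends up both more effective (+1.08 QALYs) and
cheaper over a discounted lifetime (−575 US$) — the high remission rate
moves patients into the cheap remission state early — so SG dominates and
the ICER is negative. With calibrated transition inputs (below) the model
instead reproduces the classic trade-off: more effective *and* more
expensive, with an ICER far below the thresholds. Sensitivity layers hang
off the same object:

```python
entries, base_inmb = model.one_way()        # tornado, sorted by width
psa = model.psa(n_iterations=1000)          # Beta/Gamma second-order draws
from remarkov import ceac
curve = ceac(psa.records, [7140, 10994, 39330])
```

There is also a CLI over the same library (`remarkov run`, `dsa`, `psa`,
`calibrate`, `make-lifetable`, `validate`), each subcommand writing CSV/JSON
outputs plus a `run_record.json` with config and output digests.

Because the national life table is not redistributed, the default table
is a synthetic Gompertz–Makeham stand-in (`remarkov.synthetic`); any real
table can be supplied as a two-column `age,qx` CSV via the config file.

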