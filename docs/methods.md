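# Methods

## Scope and model overview

This package re-implements, as a tested pipeline, the economic evaluation
of contrast-enhanced MR-mammography (MRM) used as the sole imaging test in
women at intermediate breast-cancer risk due to dense breast tissue. The
evaluation has two layers:

1. **A diagnostic decision tree.** A screened woman lands in one of four
   branches — true positive (TP), false negative (FN), true negative (TN),
   false positive (FP) — with probabilities determined by the pre-test
   probability of malignancy `p`, test sensitivity `Se` and specificity
   `Sp`:

   `P(TP) = p·Se`, `P(FN) = p·(1−Se)`, `P(TN) = (1−p)·Sp`,
   `P(FP) = (1−p)·(1−Sp)`.

   Biopsy after a positive MRM is assumed perfectly accurate, so FP
   patients are correctly ruled out at the cost of the biopsy and a
   one-time 0.05 QALY loss.

2. **A Markov cohort model per branch** over yearly cycles and a 5-year
   horizon, with an absorbing death state. Expected costs and QALYs per
   branch are rolled back through the tree to the base case; net monetary
   benefit is `NMB = WTP·QALYs − cost` at a willingness to pay of
   100,000 €/QALY.

## States

The published model distinguishes "alive without malignancy", "alive with
malignancy" and "dead". Internally we use four states — `no_cancer`,
`cancer_untreated`, `cancer_recurrent`, `dead` — because the one-time
surgery cost charged when a cancer is treated successfully differs between
a first (delayed) treatment and the re-treatment of a recurrence, and a
single cancer state cannot carry two different costs on the same
transition. The two cancer compartments share utilities (0.7), yearly
costs (10,000 €) and transition probabilities (60 %/yr treatment success,
5.44 %/yr cancer death), so their combined occupancy equals the
three-state model's cancer occupancy exactly.

Mortality is state-specific: cancer states use the cancer death
probability alone; the no-cancer state uses age-dependent background
(life-table) mortality. The bundled default table is a constant
0.0007/yr for ages 32–36 — a synthetic stand-in on the order of national
female life-table rates at these ages, overridable with a CSV
(`age,annual_death_probability`); over a 5-year horizon its effect on all
outputs is below 0.01 QALY.

## Branch structure and default parameters

| Branch | Start state | Upfront (undiscounted) | Notes |
|---|---|---|---|
| TP | `no_cancer` | MRM 418.50 + biopsy 300 + early surgery 4000 | immediate successful treatment assumed; recurrence risk 4.5 %/yr active |
| FN | `cancer_untreated` | MRM 418.50 | treatment success 60 %/yr triggers delayed surgery 10,000 (timing configurable, below); recurrence active after treatment |
| TN | `no_cancer` | MRM 418.50 | follow-up surveillance MRMs within the horizon |
| FP | `no_cancer` | MRM + biopsy 718.50; −0.05 QALY | otherwise identical to TN by construction |

Because FP is defined as TN plus the biopsy, `cost(FP) − cost(TN) =
300.00 €` and `QALY(FP) − QALY(TN) = −0.05` hold algebraically under every
convention; the calibration search asserts this identity on every grid
point.

## Discounting and accrual conventions

Costs and QALYs are discounted at 3 %/yr. The engine supports three
timing conventions: `begin` (cycle *t* discounted by `(1+r)^−t`, rewards
on start-of-cycle occupancy; the default), `end` (`(1+r)^−(t+1)`,
end-of-cycle occupancy) and `half` (`(1+r)^−(t+0.5)`, averaged occupancy —
the classical half-cycle correction). A separate flag forces occupancy
averaging under any timing. One-time transition costs are charged in the
cycle the transition occurs, using that cycle's discount factor. Upfront
acute costs and one-time utility decrements are added undiscounted.

## Convention calibration

The original analysis was built in commercial decision-tree software
whose cycle-reward settings are not documented, so per-branch values can
only be reproduced up to a set of discrete conventions. Three structural
questions are genuinely open in the source description and are exposed as
knobs, grid-searched in `calibrate_conventions` against the reported
branch values (summed relative error over the four branches' costs and
QALYs):

* **TN/FP follow-up.** The reported TN cost (1193.16 €) exceeds a single
  MRM fee (418.50 €); negative cases were followed by MR for five years,
  so TN/FP patients receive scheduled surveillance MRMs (`none`, `annual`
  = years 1–4, or `biennial` = years 2 and 4; default biennial).
* **Recurrence scope and cost.** By default only patients with a treated
  cancer (TP; FN after successful treatment) can recur (4.5 %/yr); a knob
  extends recurrence to TN/FP. The surgery charged when a recurrence is
  treated is `none`, `early` (default) or `delayed`.
* **FN delayed-surgery timing.** The spec-level default charges the
  10,000 € delayed surgery on each first-treatment success transition
  (`on_success`). Under any timing convention this, combined with the
  10,000 €/yr cost of living with cancer, overshoots the reported FN
  total by ~50 %: the reported value is arithmetically consistent only
  with the surgery being charged once at the start of the delayed-care
  pathway. The `upfront` option therefore charges it once, undiscounted,
  at cycle 0 — equivalent to folding the surgery into the acute cost of a
  missed diagnosis.

The best fit on the 216-point grid is `end` discounting, no extra
half-cycle correction, recurrence restricted to treated cancer with
early-surgery re-treatment cost, biennial surveillance and upfront FN
surgery. Its worst per-branch relative error is 3.65 % (TP cost); all
eight branch quantities are within 5 % of the reported values. The
residual is reported, never silently absorbed: base-case and sensitivity
analyses that check published numbers run in "branch-values" mode, with
the published per-branch values as fixed inputs, which makes them exact
and independent of engine conventions.

Defaults elsewhere follow the study inputs directly (prevalence 7 %,
Se 100 %, Sp 97 %, start age 32, horizon 5 years, WTP 100,000 €/QALY).
The β/γ distribution tags on the inputs are carried as metadata for
completeness; no probabilistic sensitivity analysis is performed because
none is reported to check against.

## One-way sensitivity analysis

Each parameter sweeps an evenly spaced 21-point grid (endpoints included)
with all others at base case. `branch-values` mode varies only the tree
probabilities (prevalence 0–20 %, Se and Sp 70–100 %) over fixed branch
values — the mode in which the published claims (cost ≤ 2500 €,
effectiveness 4.68–4.70 QALYs) are reproduced — while `full-model` mode
re-evaluates the branch Markov models and can vary any numeric parameter
(e.g. the MRM fee ±50 %). Tree responses are linear in each probability,
so extremes occur at range endpoints; the grid is still evaluated and the
recorded extremes are taken over it. Tornado ordering sorts by the
endpoint cost swing `|cost(high) − cost(low)|`, stable for ties.

## Microsimulation

The patient-level simulator draws each patient's branch from the tree
probabilities and walks them through the same transition matrices and
accrual conventions as the cohort engine, with a single seeded numpy
generator and cycle-synchronous vectorised sampling (bit-reproducible
under a fixed seed; no per-patient streams are needed because nothing
runs in parallel). It plays two roles: a generator of synthetic cohorts
with the statistical structure the analysis assumes (including a
per-patient diagnostic-study table with true status and test result),
and a Monte-Carlo oracle — per-branch means converge to the cohort
expectations, checked at n = 200,000 within 3 standard errors. What it
deliberately does not emulate: patient heterogeneity beyond the branch
assignment, stage-specific tumour progression, and correlated test
errors; agreement therefore validates the engine's arithmetic, not the
clinical realism of the inputs.

## Numerical choices and degenerate inputs

* Transition-matrix rows must sum to 1 within 1e-9; violations name the
  offending state and cycle. Occupancy conservation is asserted to 1e-9.
* Metrics with zero denominators (e.g. sensitivity with no diseased
  patients) are explicit missing values plus a warning, never zero.
* All quantities are computed and stored at full precision; rounding to
  two decimals (€ and QALYs) happens only in reporting columns.
* Calibration ties (settings with identical error) resolve to the first
  candidate in the fixed grid order.
* Reports contain no timestamps, so a rerun with the same configuration
  and seed is byte-identical.

## Problem sizes

Default checks use 200 randomized 3-state models for the conservation
properties, 200,000 patients for the oracle comparison, 100,000 for
binomial convergence checks, and the 216-point convention grid —
together a few seconds on one core.

## Known limitations

* The reported TP QALY value (4.62) sits 0.03 below TN minus the biopsy
  loss (4.65); whether this stems from recurrence time at utility 0.7 or
  an unstated treatment disutility cannot be decided from the source, so
  the calibrated model reproduces it only approximately.
* Only the MRM strategy is modelled; no comparator strategy or ICER is
  computed (the source analysis is explicitly non-comparative).
* Whether utilities accrue in the cycle of death is convention-dependent;
  it is covered by the discount-timing knob rather than resolved.
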