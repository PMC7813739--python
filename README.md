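# mrm-cea

Cost-effectiveness analysis of MR-mammography (MRM) as a stand-alone
imaging test for women at intermediate breast-cancer risk due to dense
breast tissue.

Conventional X-ray mammography loses accuracy in dense breasts. A
prospective screening cohort (1095 evaluated women, 7 % pre-test
probability of malignancy) found MRM alone to be highly accurate
(sensitivity 100 %, specificity 97 % at the model level). This package
asks the follow-up economic question: *what do 5 years of costs and
quality-adjusted life expectancy look like under MRM-based screening, and
is the strategy affordable at a conventional willingness to pay?*

The model is a diagnostic decision tree feeding Markov cohort models.
Each screened woman falls into a branch with probability

    P(TP) = p·Se,   P(FN) = p·(1−Se),   P(TN) = (1−p)·Sp,   P(FP) = (1−p)·(1−Sp)

and each branch is a discrete-time Markov model over the health states
*alive without malignancy*, *alive with malignancy* and *dead* (yearly
cycles, 5-year horizon, costs and utilities discounted at 3 %/yr).
Rolling the tree back gives expected cost `E[C] = Σ_b P(b)·C_b`, expected
effectiveness `E[Q] = Σ_b P(b)·Q_b`, and net monetary benefit
`NMB = λ·E[Q] − E[C]` at willingness to pay λ = 100,000 €/QALY.
A patient-level microsimulation with the same transition structure acts
as synthetic-data generator and as a Monte-Carlo oracle for the cohort
engine, and a one-way deterministic sensitivity analysis (tornado)
quantifies which inputs drive costs and effectiveness.

## Worked example

```python
from mrm_cea import TKParameters, base_case, qaly_gain, tree_probabilities
from mrm_cea.reference import REPORTED_BRANCH_RESULTS

params = TKParameters()                # study inputs: p=0.07, Se=1.0, Sp=0.97, ...
probs = tree_probabilities(params)
bc = base_case(REPORTED_BRANCH_RESULTS, probs, params.wtp)
print(f"{bc.expected_cost:.2f} EUR, {bc.expected_qalys:.2f} QALYs, NMB {bc.nmb:.2f} EUR")
print(f"TP-vs-FN gain: {qaly_gain(REPORTED_BRANCH_RESULTS, 'TP', 'FN'):.2f} QALYs")
```

prints

```
1650.48 EUR, 4.69 QALYs, NMB 467650.02 EUR
TP-vs-FN gain: 0.67 QALYs
```

i.e. a screened woman costs an expected 1650.48 € over five years for an
expected 4.69 QALYs — comfortably acceptable at the 100,000 €/QALY
threshold (positive NMB) — and a timely diagnosis (TP) beats a missed one
(FN) by 0.67 QALYs while also costing far less, because delayed
diagnoses carry more extensive surgery and longer time with disease.

The numbered drivers under `analysis/` run the full study pipeline and
write their tables to `results/`:

| script | what it does |
|---|---|
| `01_diagnostic_accuracy.py` | test-performance metrics from the cohort's confusion counts |
| `02_branch_models.py` | per-branch Markov outcomes + engine-convention calibration |
| `03_base_case.py` | decision-tree base case and NMB |
| `04_sensitivity_analysis.py` | one-way DSA, tornado-ordered |
| `05_microsim_check.py` | 200k-patient microsimulation vs. cohort engine |

The same stages are available as a CLI (`mrm-cea accuracy|basecase|dsa|
microsim|calibrate|run-all`, each taking `--config <yaml>` and `--out`),
and `docs/methods.md` documents the model, its conventions and their
calibration in detail.

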