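"""Published reference values of the TK-Study MRM evaluation.

These are the numbers reported by the original analysis (diagnostic
confusion counts of the screening cohort, and the per-branch expected
costs/QALYs computed with commercial decision-tree software).  They serve
two roles in this package:

* fixed branch inputs for the decision-tree stage ("branch-values" mode),
  which reproduces the published base case and sensitivity analyses
  exactly, independently of Markov engine conventions; and
* the reference against which :func:`mrm_cea.model.calibrate_conventions`
  scores its convention grid.

They are inputs to the pipeline, never outputs of it.
"""

from __future__ import annotations

from .accuracy import ConfusionCounts
from .model import BranchResult

__all__ = [
    "TK_CONFUSION",
    "TK_CONFUSION_INVASIVE",
    "REPORTED_BRANCH_RESULTS",
    "REPORTED_BASE_CASE_COST",
    "REPORTED_BASE_CASE_QALYS",
    "REPORTED_DSA_RANGES",
]

#: Screening cohort of 1095 evaluated women (all malignancies).
TK_CONFUSION = ConfusionCounts(tp=76, fp=48, tn=971, fn=0)

#: Same cohort restricted to invasive cancers (DCIS excluded).
TK_CONFUSION_INVASIVE = ConfusionCounts(tp=63, fp=27, tn=971, fn=0)

#: Per-branch 5-year discounted expected cost (EUR) and QALYs as reported.
REPORTED_BRANCH_RESULTS: dict[str, BranchResult] = {
    "TP": BranchResult("TP", expected_cost=7606.80, expected_qalys=4.62),
    "FN": BranchResult("FN", expected_cost=17_518.54, expected_qalys=3.95),
    "TN": BranchResult("TN", expected_cost=1193.16, expected_qalys=4.70),
    "FP": BranchResult("FP", expected_cost=1493.16, expected_qalys=4.65),
}

#: Reported base-case expectation over the decision tree.
REPORTED_BASE_CASE_COST = 1650.48
REPORTED_BASE_CASE_QALYS = 4.69

#: One-way sensitivity ranges reported for the tree probabilities.
REPORTED_DSA_RANGES: dict[str, tuple[float, float]] = {
    "prevalence": (0.0, 0.20),
    "sensitivity_mrm": (0.70, 1.00),
    "specificity_mrm": (0.70, 1.00),
}
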