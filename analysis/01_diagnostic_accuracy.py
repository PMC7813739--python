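#!/usr/bin/env python
"""Diagnostic performance of MR-mammography in the screening cohort.

Computes sensitivity, specificity, PPV, NPV, accuracy and prevalence from
the study's confusion counts — the full cohort of 1095 evaluated women
and the invasive-only subset (DCIS excluded) — and writes one row per
cohort to results/accuracy.csv.
"""

from pathlib import Path

import pandas as pd

from mrm_cea.accuracy import compute_performance
from mrm_cea.reference import TK_CONFUSION, TK_CONFUSION_INVASIVE

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for cohort, counts in (
        ("all_malignancies", TK_CONFUSION),
        ("invasive_only", TK_CONFUSION_INVASIVE),
    ):
        perf = compute_performance(counts)
        rows.append(
            {
                "cohort": cohort,
                "tp": counts.tp, "fp": counts.fp,
                "tn": counts.tn, "fn": counts.fn,
                **{k: v for k, v in perf.as_dict().items()},
            }
        )
        print(
            f"{cohort}: sensitivity {100 * perf.sensitivity:.1f}%, "
            f"specificity {100 * perf.specificity:.1f}%, "
            f"PPV {100 * perf.ppv:.1f}%, NPV {100 * perf.npv:.1f}%, "
            f"accuracy {100 * perf.accuracy:.1f}%"
        )
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "accuracy.csv", index=False)
    print(f"wrote {OUT / 'accuracy.csv'}")


if __name__ == "__main__":
    main()
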