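#!/usr/bin/env python
"""One-way deterministic sensitivity analysis (tornado-ordered).

Sweeps prevalence (0-20%), MRM sensitivity and specificity (70-100%) one
at a time over the decision tree with branch values fixed at the reported
results, and additionally varies the MRM fee +/-50% through the full
Markov model.  Writes the tornado-ordered table to results/dsa.csv.
"""

from pathlib import Path

import pandas as pd

from mrm_cea.decision import one_way_dsa, tornado_order
from mrm_cea.model import TKParameters
from mrm_cea.reference import REPORTED_BRANCH_RESULTS, REPORTED_DSA_RANGES

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = TKParameters()
    tree = one_way_dsa(
        params, REPORTED_DSA_RANGES, branch_results=REPORTED_BRANCH_RESULTS
    )
    fee = one_way_dsa(
        params,
        {"cost_mrm": (params.cost_mrm * 0.5, params.cost_mrm * 1.5)},
        mode="full-model",
        n_points=5,
    )
    table = tornado_order(pd.concat([tree, fee], ignore_index=True))
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "dsa.csv", index=False)

    print(table[["parameter", "low", "high", "cost_min", "cost_max",
                 "qaly_min", "qaly_max", "swing"]].to_string(index=False))
    print(
        f"\nmax expected cost over all sweeps: "
        f"{table['cost_max'].max():.2f} EUR (bound: 2500 EUR)"
    )
    print(
        f"expected QALYs range: {table['qaly_min'].min():.2f} - "
        f"{table['qaly_max'].max():.2f}"
    )
    print(f"cost driver ranking: {', '.join(table['parameter'])}")


if __name__ == "__main__":
    main()
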