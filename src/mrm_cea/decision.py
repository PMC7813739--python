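"""Decision-tree roll-back, net monetary benefit and one-way sensitivity
analysis.

The four branch models yield expected cost and QALYs per branch; the
decision tree weights them by the branch probabilities implied by
prevalence, sensitivity and specificity.  One-way deterministic
sensitivity analysis (DSA) re-evaluates the tree while a single parameter
sweeps a range, all others held at base case; a tornado ordering ranks
parameters by the induced cost swing.

DSA runs in one of two modes:

``branch-values``
    The per-branch costs/QALYs are fixed inputs (e.g. the published
    values) and only the tree probabilities vary.  Only ``prevalence``,
    ``sensitivity_mrm`` and ``specificity_mrm`` can be swept.
``full-model``
    The branch Markov models are re-evaluated at every grid point, so any
    numeric model parameter (costs, utilities, transition probabilities)
    can be swept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .accuracy import BranchProbabilities, branch_probabilities
from .model import BRANCHES, BranchResult, Conventions, TKParameters, \
    evaluate_all_branches

__all__ = [
    "BaseCaseResult",
    "base_case",
    "qaly_gain",
    "tree_probabilities",
    "one_way_dsa",
    "tornado_order",
    "TREE_PARAMETERS",
]

#: Parameters that act on the decision tree only (branch-values mode).
TREE_PARAMETERS = ("prevalence", "sensitivity_mrm", "specificity_mrm")


@dataclass(frozen=True)
class BaseCaseResult:
    """Probability-weighted expectation over the four branches."""

    expected_cost: float
    expected_qalys: float
    nmb: float
    wtp: float


def _check_results(branch_results: Mapping[str, BranchResult]) -> None:
    missing = [b for b in BRANCHES if b not in branch_results]
    if missing:
        raise ValueError(f"branch results missing for {missing}")


def base_case(
    branch_results: Mapping[str, BranchResult],
    branch_probs: BranchProbabilities,
    wtp: float,
) -> BaseCaseResult:
    """Roll the decision tree back to expected cost, QALYs and NMB.

    NMB (net monetary benefit) = WTP x QALYs - cost; positive values mean
    the strategy is acceptable at the given willingness-to-pay threshold.
    """
    _check_results(branch_results)
    if not isinstance(branch_probs, BranchProbabilities):
        raise TypeError("branch_probs must be a BranchProbabilities instance")
    probs = branch_probs.as_dict()
    cost = sum(probs[b] * branch_results[b].expected_cost for b in BRANCHES)
    qalys = sum(probs[b] * branch_results[b].expected_qalys for b in BRANCHES)
    return BaseCaseResult(
        expected_cost=cost,
        expected_qalys=qalys,
        nmb=wtp * qalys - cost,
        wtp=wtp,
    )


def qaly_gain(
    branch_results: Mapping[str, BranchResult], a: str, b: str
) -> float:
    """QALY difference between two branches (a minus b), full precision."""
    for label in (a, b):
        if label not in branch_results:
            raise ValueError(f"unknown branch {label!r}")
    return (
        branch_results[a].expected_qalys - branch_results[b].expected_qalys
    )


def tree_probabilities(params: TKParameters) -> BranchProbabilities:
    """Branch probabilities implied by the model parameters."""
    return branch_probabilities(
        params.prevalence, params.sensitivity_mrm, params.specificity_mrm
    )


def _evaluate_point(
    params: TKParameters,
    mode: str,
    branch_results: Mapping[str, BranchResult] | None,
    conventions: Conventions,
) -> tuple[float, float]:
    if mode == "branch-values":
        results = branch_results
    else:
        results = evaluate_all_branches(params, conventions)
    assert results is not None
    bc = base_case(results, tree_probabilities(params), params.wtp)
    return bc.expected_cost, bc.expected_qalys


def one_way_dsa(
    params: TKParameters,
    ranges: Mapping[str, tuple[float, float]],
    n_points: int = 21,
    mode: str = "branch-values",
    branch_results: Mapping[str, BranchResult] | None = None,
    conventions: Conventions = Conventions(),
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis.

    Each parameter in ``ranges`` sweeps an evenly spaced grid (endpoints
    included) while all others stay at base case.  Returns one row per
    parameter with values at both endpoints, the grid extremes, and the
    endpoint cost swing used for tornado ordering.  For the tree
    probabilities the response is linear, so extremes occur at endpoints.

    Raises if a range leaves the parameter's legal domain or if a
    non-tree parameter is requested in branch-values mode.
    """
    if mode not in ("branch-values", "full-model"):
        raise ValueError(f"unknown DSA mode {mode!r}")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if mode == "branch-values":
        if branch_results is None:
            raise ValueError("branch-values mode requires branch_results")
        _check_results(branch_results)

    rows = []
    for name, (low, high) in ranges.items():
        if mode == "branch-values" and name not in TREE_PARAMETERS:
            raise ValueError(
                f"{name!r} does not act on the decision tree; "
                "use full-model mode to vary it"
            )
        if low > high:
            raise ValueError(f"range for {name!r} has low > high")
        grid = np.linspace(low, high, n_points) if low < high else np.array([low])
        costs = np.empty(grid.size)
        qalys = np.empty(grid.size)
        for i, value in enumerate(grid):
            try:
                varied = params.with_overrides(**{name: float(value)})
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"range for {name!r} leaves its legal domain: {exc}"
                ) from exc
            costs[i], qalys[i] = _evaluate_point(
                varied, mode, branch_results, conventions
            )
        rows.append(
            {
                "parameter": name,
                "low": low,
                "high": high,
                "cost_low": costs[0],
                "cost_high": costs[-1],
                "qaly_low": qalys[0],
                "qaly_high": qalys[-1],
                "cost_min": costs.min(),
                "cost_max": costs.max(),
                "qaly_min": qalys.min(),
                "qaly_max": qalys.max(),
                "swing": abs(costs[-1] - costs[0]),
            }
        )
    return pd.DataFrame(rows)


def tornado_order(dsa: pd.DataFrame) -> pd.DataFrame:
    """Order a DSA table by descending cost swing (stable for ties)."""
    if dsa.empty:
        raise ValueError("DSA table is empty")
    return dsa.sort_values(
        "swing", ascending=False, kind="stable"
    ).reset_index(drop=True)
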