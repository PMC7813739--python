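"""Patient-level microsimulation of the screening decision tree.

Each simulated patient is assigned a decision-tree branch (TP/FN/TN/FP)
from the branch probabilities, then walks year by year through the same
transition matrices as the cohort engine, accruing discounted costs and
QALYs under the same accrual conventions.  Per-branch and overall means
therefore converge to the cohort-model expectations (law of large
numbers), which makes the microsimulation a Monte-Carlo oracle for
:func:`mrm_cea.markov.run_cohort`.

Sampling is cycle-synchronous and fully vectorised over patients with a
single seeded generator, so runs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accuracy import ConfusionCounts
from .decision import tree_probabilities
from .markov import DiscountSpec, MarkovSpec, discount_factor
from .model import BRANCHES, BranchModel, Conventions, TKParameters, build_branch

__all__ = [
    "MicrosimSummary",
    "simulate_paths",
    "simulate_branch_cohort",
    "simulate_cohort",
    "generate_study_dataset",
]

#: Default cap on exported per-patient trajectories.
MAX_TRAJECTORY_PATIENTS = 10_000


@dataclass
class MicrosimSummary:
    """Per-branch and overall Monte-Carlo summaries.

    ``table`` has one row per branch plus an ``overall`` row with columns
    ``n``, ``mean_cost``, ``se_cost``, ``mean_qalys``, ``se_qalys``
    (SE = sample SD / sqrt(n); NaN for n < 2).
    """

    table: pd.DataFrame
    trajectories: pd.DataFrame | None = None


def _sample_transitions(
    states_t: np.ndarray, matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw next states for all patients given their current states."""
    nxt = np.empty_like(states_t)
    u = rng.random(states_t.size)
    for s in np.unique(states_t):
        mask = states_t == s
        cum = np.cumsum(matrix[s])
        nxt[mask] = np.searchsorted(cum, u[mask], side="right")
    return np.minimum(nxt, matrix.shape[0] - 1)


def simulate_paths(
    model: BranchModel,
    n: int,
    horizon: int,
    discount: DiscountSpec,
    rng: np.random.Generator,
    half_cycle_correction: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n`` patients through one branch model.

    Returns ``(costs, qalys, states)`` where ``states`` has shape
    ``(n, horizon + 1)`` (state index per patient per cycle start) and the
    accruals replicate the cohort engine's conventions exactly, including
    the branch's upfront cost and one-time utility adjustment.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    spec: MarkovSpec = model.spec
    states = np.empty((n, horizon + 1), dtype=np.int64)
    states[:, 0] = spec.state_index(model.start_state)
    costs = np.full(n, model.upfront_cost, dtype=float)
    qalys = np.full(n, model.upfront_utility_adjustment, dtype=float)
    utilities = np.asarray(spec.state_utilities, dtype=float)
    trans_cost = spec.transition_cost_matrix()

    for t in range(horizon):
        matrix = spec.matrix_at(t)
        states[:, t + 1] = _sample_transitions(states[:, t], matrix, rng)
        factor = discount_factor(discount.annual_rate, t, discount.convention)
        cvec = spec.costs_at(t)
        if discount.convention == "half" or half_cycle_correction:
            cost_w = 0.5 * (cvec[states[:, t]] + cvec[states[:, t + 1]])
            util_w = 0.5 * (utilities[states[:, t]] + utilities[states[:, t + 1]])
        elif discount.convention == "end":
            cost_w = cvec[states[:, t + 1]]
            util_w = utilities[states[:, t + 1]]
        else:
            cost_w = cvec[states[:, t]]
            util_w = utilities[states[:, t]]
        costs += factor * (cost_w + trans_cost[states[:, t], states[:, t + 1]])
        qalys += factor * util_w
    return costs, qalys, states


def _summary_row(label: str, costs: np.ndarray, qalys: np.ndarray) -> dict:
    n = costs.size
    row = {"group": label, "n": n}
    if n == 0:
        row.update(mean_cost=np.nan, se_cost=np.nan,
                   mean_qalys=np.nan, se_qalys=np.nan)
    else:
        row["mean_cost"] = float(costs.mean())
        row["mean_qalys"] = float(qalys.mean())
        if n >= 2:
            row["se_cost"] = float(costs.std(ddof=1) / np.sqrt(n))
            row["se_qalys"] = float(qalys.std(ddof=1) / np.sqrt(n))
        else:
            row["se_cost"] = np.nan
            row["se_qalys"] = np.nan
    return row


def simulate_branch_cohort(
    branch: str,
    params: TKParameters,
    conventions: Conventions,
    n: int,
    seed: int | np.random.Generator | None,
) -> pd.DataFrame:
    """Monte-Carlo summary for ``n`` patients all entering one branch."""
    rng = np.random.default_rng(seed)
    model = build_branch(branch, params, conventions)
    discount = DiscountSpec(params.discount_rate, conventions.discount_timing)
    costs, qalys, _ = simulate_paths(
        model, n, params.horizon, discount, rng,
        conventions.half_cycle_correction,
    )
    return pd.DataFrame([_summary_row(branch, costs, qalys)])


def simulate_cohort(
    params: TKParameters,
    conventions: Conventions = Conventions(),
    n: int = 100_000,
    seed: int | np.random.Generator | None = None,
    collect_trajectories: bool = False,
    max_trajectories: int = MAX_TRAJECTORY_PATIENTS,
) -> MicrosimSummary:
    """Simulate a full screening cohort through the decision tree.

    Each patient's branch is drawn from the tree probabilities; yearly
    transitions are drawn from the branch's transition matrices.  Returns
    per-branch and overall summaries and, optionally, per-patient
    trajectories for at most ``max_trajectories`` patients.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    probs = tree_probabilities(params)
    p = np.array([probs.as_dict()[b] for b in BRANCHES])
    branch_idx = rng.choice(len(BRANCHES), size=n, p=p)
    discount = DiscountSpec(params.discount_rate, conventions.discount_timing)

    all_costs = np.empty(n)
    all_qalys = np.empty(n)
    rows = []
    traj_frames: list[pd.DataFrame] = []
    for bi, branch in enumerate(BRANCHES):
        mask = branch_idx == bi
        m = int(mask.sum())
        if m == 0:
            rows.append(_summary_row(branch, np.empty(0), np.empty(0)))
            continue
        model = build_branch(branch, params, conventions)
        costs, qalys, states = simulate_paths(
            model, m, params.horizon, discount, rng,
            conventions.half_cycle_correction,
        )
        all_costs[mask] = costs
        all_qalys[mask] = qalys
        rows.append(_summary_row(branch, costs, qalys))
        if collect_trajectories:
            ids = np.flatnonzero(mask)[:max_trajectories]
            keep = ids.size
            labels = np.asarray(model.spec.states)
            traj_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": np.repeat(ids, params.horizon + 1),
                        "branch": branch,
                        "cycle": np.tile(
                            np.arange(params.horizon + 1), keep
                        ),
                        "state": labels[states[:keep]].ravel(),
                    }
                )
            )
    rows.append(_summary_row("overall", all_costs, all_qalys))
    table = pd.DataFrame(rows)

    trajectories = None
    if collect_trajectories:
        trajectories = (
            pd.concat(traj_frames, ignore_index=True)
            if traj_frames
            else pd.DataFrame(
                columns=["patient_id", "branch", "cycle", "state"]
            )
        )
        if len(trajectories) > 0:
            trajectories = (
                trajectories.sort_values(["patient_id", "cycle"])
                .head(max_trajectories * (params.horizon + 1))
                .reset_index(drop=True)
            )
    return MicrosimSummary(table=table, trajectories=trajectories)


def generate_study_dataset(
    params: TKParameters,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, ConfusionCounts]:
    """Generate a synthetic diagnostic-study table of ``n`` patients.

    Disease status is Bernoulli(prevalence); the MRM result is
    Bernoulli(sensitivity) for diseased and positive with probability
    1 - specificity for healthy patients.  Returns the per-patient table
    (true status, test result, classification) and its confusion counts.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    diseased = rng.random(n) < params.prevalence
    u = rng.random(n)
    positive = np.where(
        diseased, u < params.sensitivity_mrm, u >= params.specificity_mrm
    )
    classification = np.where(
        diseased,
        np.where(positive, "TP", "FN"),
        np.where(positive, "FP", "TN"),
    )
    table = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "diseased": diseased,
            "test_positive": positive,
            "classification": classification,
        }
    )
    counts = ConfusionCounts(
        tp=int(np.sum(classification == "TP")),
        fp=int(np.sum(classification == "FP")),
        tn=int(np.sum(classification == "TN")),
        fn=int(np.sum(classification == "FN")),
    )
    return table, counts
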