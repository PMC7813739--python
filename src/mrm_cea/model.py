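"""Diagnostic-branch Markov models for MR-mammography screening.

Women with dense breast tissue screened with MR-mammography (MRM) fall
into four decision-tree branches according to the test result versus
ground truth: true positive (TP), false negative (FN), true negative (TN)
and false positive (FP).  Each branch is modelled as a Markov cohort over
yearly cycles with the health states

* ``no_cancer``          — alive, no malignancy present (treated or never ill)
* ``cancer_untreated``   — alive with an undiagnosed malignancy (FN start)
* ``cancer_recurrent``   — alive with a recurrence after treatment
* ``dead``               — absorbing

The published three-state formulation ("alive without cancer", "alive
with cancer", "dead") is recovered by merging the two cancer
compartments, which share costs, utilities and transition probabilities;
they are kept separate here only so that the one-time surgery cost charged
on treatment success can differ between a first (delayed) treatment and
the re-treatment of a recurrence.

Branch structure
----------------
TP  starts in ``no_cancer`` (immediate successful treatment assumed);
    acute costs MRM + biopsy + early surgery; recurrence risk active.
FN  starts in ``cancer_untreated``; acute cost MRM only; treatment
    success (60 %/yr) leads to ``no_cancer`` and incurs the delayed
    (more extensive) surgery; recurrence risk active after treatment.
TN  starts in ``no_cancer``; acute cost MRM; follow-up surveillance MRMs
    within the horizon (schedule configurable).
FP  identical to TN plus the biopsy cost upfront and a one-time QALY
    loss for the (benign) biopsy.

Mortality: the cancer states use the cancer-specific annual death
probability alone; the no-cancer state uses age-dependent background
(life-table) mortality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .markov import CohortResult, DiscountSpec, MarkovSpec, run_cohort

__all__ = [
    "STATES",
    "BRANCHES",
    "TKParameters",
    "Conventions",
    "BranchModel",
    "BranchResult",
    "build_branch",
    "evaluate_branch",
    "evaluate_all_branches",
    "CalibrationResult",
    "calibrate_conventions",
]

STATES = ("no_cancer", "cancer_untreated", "cancer_recurrent", "dead")
BRANCHES = ("TP", "FN", "TN", "FP")

#: Distribution families attached to each parameter for probabilistic
#: analyses (metadata only; the deterministic pipeline never samples them).
DEFAULT_DISTRIBUTIONS: Mapping[str, str] = {
    "prevalence": "beta",
    "sensitivity_mrm": "beta",
    "specificity_mrm": "beta",
    "biopsy_sensitivity": "beta",
    "biopsy_specificity": "beta",
    "cost_mrm": "gamma",
    "cost_biopsy": "gamma",
    "cost_early_surgery": "gamma",
    "cost_delayed_surgery": "gamma",
    "yearly_cost_tumor": "gamma",
    "yearly_cost_no_tumor": "gamma",
    "utility_no_tumor": "beta",
    "utility_tumor": "beta",
    "utility_dead": "beta",
    "qaly_loss_biopsy": "beta",
    "p_death_tumor": "beta",
    "p_recurrence": "beta",
    "p_treatment_success": "beta",
}


def _default_background_mortality() -> dict[int, float]:
    # Constant life-table stand-in for women aged 32-36 (order of magnitude
    # of US female rates); override via p_death_background or a CSV table.
    return {age: 0.0007 for age in range(32, 37)}


@dataclass(frozen=True)
class TKParameters:
    """All model inputs of the screening evaluation, with study defaults.

    Probabilities are annual; costs are in euros; utilities are QALY
    weights in [0, 1].  ``p_death_background`` maps age (years) to the
    annual probability of death without cancer; ages outside the table are
    clamped to the nearest tabulated age.
    """

    prevalence: float = 0.07
    sensitivity_mrm: float = 1.00
    specificity_mrm: float = 0.97
    biopsy_sensitivity: float = 1.00
    biopsy_specificity: float = 1.00
    cost_mrm: float = 418.50
    cost_biopsy: float = 300.00
    cost_early_surgery: float = 4000.00
    cost_delayed_surgery: float = 10000.00
    yearly_cost_tumor: float = 10000.00
    yearly_cost_no_tumor: float = 0.00
    utility_no_tumor: float = 1.0
    utility_tumor: float = 0.7
    utility_dead: float = 0.0
    qaly_loss_biopsy: float = 0.05
    p_death_tumor: float = 0.0544
    p_death_background: Mapping[int, float] = field(
        default_factory=_default_background_mortality
    )
    p_recurrence: float = 0.045
    p_treatment_success: float = 0.60
    start_age: int = 32
    horizon: int = 5
    discount_rate: float = 0.03
    wtp: float = 100_000.0
    distribution_family: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DISTRIBUTIONS)
    )

    def __post_init__(self) -> None:
        proportions = (
            "prevalence", "sensitivity_mrm", "specificity_mrm",
            "biopsy_sensitivity", "biopsy_specificity", "utility_no_tumor",
            "utility_tumor", "utility_dead", "qaly_loss_biopsy",
            "p_death_tumor", "p_recurrence", "p_treatment_success",
        )
        for name in proportions:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        costs = (
            "cost_mrm", "cost_biopsy", "cost_early_surgery",
            "cost_delayed_surgery", "yearly_cost_tumor", "yearly_cost_no_tumor",
        )
        for name in costs:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.utility_dead != 0.0:
            raise ValueError("utility_dead must be 0")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.wtp < 0:
            raise ValueError("wtp must be >= 0")
        if self.p_treatment_success + self.p_death_tumor > 1.0 + 1e-12:
            raise ValueError(
                "p_treatment_success + p_death_tumor must not exceed 1"
            )
        if not self.p_death_background:
            raise ValueError("p_death_background table must not be empty")
        for age, p in self.p_death_background.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"background death probability at age {age} must be in [0, 1]"
                )

    def background_mortality_at(self, age: int) -> float:
        """Annual background death probability, clamped to the table range."""
        table = self.p_death_background
        if age in table:
            return table[age]
        ages = sorted(table)
        clamped = min(max(age, ages[0]), ages[-1])
        if clamped in table:
            return table[clamped]
        below = [a for a in ages if a <= clamped]
        return table[below[-1]] if below else table[ages[0]]

    def with_overrides(self, **overrides) -> "TKParameters":
        return replace(self, **overrides)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_RECURRENCE_COSTS = ("none", "early", "delayed")
_SURVEILLANCE = ("none", "annual", "biennial")
_FN_TIMING = ("on_success", "upfront")
_TIMINGS = ("begin", "end", "half")


@dataclass(frozen=True)
class Conventions:
    """Discrete modelling conventions left open by the published analysis.

    These knobs span the calibration grid of :func:`calibrate_conventions`.

    discount_timing
        Reward-accrual/discount convention of the cohort engine.
    half_cycle_correction
        Average start/end occupancy for rewards (on top of the timing).
    recurrence_tn_fp
        Whether the recurrence risk also applies to TN/FP patients
        (default: only patients with a treated cancer can recur).
    recurrence_event_cost
        Surgery cost charged when a recurrence is treated successfully:
        ``none`` (0), ``early`` or ``delayed``.
    surveillance
        Follow-up MRM schedule for TN/FP patients within the horizon:
        ``none``, ``annual`` (years 1..horizon-1) or ``biennial``
        (every other year starting at year 2).
    fn_surgery_timing
        When the FN branch pays the delayed surgery: ``on_success``
        (charged on each first-treatment success transition) or
        ``upfront`` (charged once, undiscounted, at cycle 0).
    """

    discount_timing: str = "begin"
    half_cycle_correction: bool = False
    recurrence_tn_fp: bool = False
    recurrence_event_cost: str = "early"
    surveillance: str = "biennial"
    fn_surgery_timing: str = "on_success"

    def __post_init__(self) -> None:
        if self.discount_timing not in _TIMINGS:
            raise ValueError(f"discount_timing must be one of {_TIMINGS}")
        if self.recurrence_event_cost not in _RECURRENCE_COSTS:
            raise ValueError(
                f"recurrence_event_cost must be one of {_RECURRENCE_COSTS}"
            )
        if self.surveillance not in _SURVEILLANCE:
            raise ValueError(f"surveillance must be one of {_SURVEILLANCE}")
        if self.fn_surgery_timing not in _FN_TIMING:
            raise ValueError(f"fn_surgery_timing must be one of {_FN_TIMING}")

    @classmethod
    def grid(cls) -> Iterator["Conventions"]:
        """All candidate settings, in a fixed deterministic order."""
        for timing, hc, rec_tnfp, rec_cost, surv, fn_timing in itertools.product(
            _TIMINGS, (False, True), (False, True), _RECURRENCE_COSTS,
            _SURVEILLANCE, _FN_TIMING,
        ):
            yield cls(
                discount_timing=timing,
                half_cycle_correction=hc,
                recurrence_tn_fp=rec_tnfp,
                recurrence_event_cost=rec_cost,
                surveillance=surv,
                fn_surgery_timing=fn_timing,
            )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class BranchModel:
    """A fully specified cohort model for one decision-tree branch."""

    branch: str
    spec: MarkovSpec
    start_state: str
    upfront_cost: float
    upfront_utility_adjustment: float


@dataclass(frozen=True)
class BranchResult:
    """Expected discounted cost (EUR) and QALYs of one branch over the horizon."""

    branch: str
    expected_cost: float
    expected_qalys: float

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ValueError(f"branch must be one of {BRANCHES}, got {self.branch!r}")


def _recurrence_cost(params: TKParameters, conventions: Conventions) -> float:
    return {
        "none": 0.0,
        "early": params.cost_early_surgery,
        "delayed": params.cost_delayed_surgery,
    }[conventions.recurrence_event_cost]


def surveillance_cycles(schedule: str, horizon: int) -> tuple[int, ...]:
    """Cycle indices in which a follow-up MRM is performed."""
    if schedule == "annual":
        return tuple(range(1, horizon))
    if schedule == "biennial":
        return tuple(range(2, horizon, 2))
    return ()


def build_branch(
    branch: str,
    params: TKParameters,
    conventions: Conventions = Conventions(),
) -> BranchModel:
    """Instantiate the Markov model of one diagnostic branch.

    See the module docstring for the branch-by-branch structure.
    """
    if branch not in BRANCHES:
        raise ValueError(f"unknown branch {branch!r}; expected one of {BRANCHES}")

    recurrence_active = branch in ("TP", "FN") or (
        branch in ("TN", "FP") and conventions.recurrence_tn_fp
    )
    p_rec = params.p_recurrence if recurrence_active else 0.0
    p_success = params.p_treatment_success
    p_death_ca = params.p_death_tumor

    def transitions(cycle: int) -> np.ndarray:
        age = params.start_age + cycle
        p_bg = params.background_mortality_at(age)
        no_cancer = np.array(
            [1.0 - p_rec - p_bg, 0.0, p_rec, p_bg]
        )
        cancer = np.array(
            [p_success, 1.0 - p_success - p_death_ca, 0.0, p_death_ca]
        )
        recurrent = np.array(
            [p_success, 0.0, 1.0 - p_success - p_death_ca, p_death_ca]
        )
        dead = np.array([0.0, 0.0, 0.0, 1.0])
        return np.vstack([no_cancer, cancer, recurrent, dead])

    base_costs = np.array(
        [params.yearly_cost_no_tumor, params.yearly_cost_tumor,
         params.yearly_cost_tumor, 0.0]
    )
    if branch in ("TN", "FP"):
        scheduled = set(surveillance_cycles(conventions.surveillance, params.horizon))

        def state_costs(cycle: int) -> np.ndarray:
            costs = base_costs.copy()
            if cycle in scheduled:
                costs[0] += params.cost_mrm
            return costs
    else:
        state_costs = base_costs  # type: ignore[assignment]

    transition_costs: dict[tuple[str, str], float] = {}
    if recurrence_active:
        rec_cost = _recurrence_cost(params, conventions)
        if rec_cost:
            transition_costs[("cancer_recurrent", "no_cancer")] = rec_cost

    upfront_utility = 0.0
    if branch == "TP":
        start = "no_cancer"
        upfront = params.cost_mrm + params.cost_biopsy + params.cost_early_surgery
    elif branch == "FN":
        start = "cancer_untreated"
        upfront = params.cost_mrm
        if conventions.fn_surgery_timing == "upfront":
            upfront += params.cost_delayed_surgery
        else:
            transition_costs[("cancer_untreated", "no_cancer")] = (
                params.cost_delayed_surgery
            )
    elif branch == "TN":
        start = "no_cancer"
        upfront = params.cost_mrm
    else:  # FP: a TN plus the (benign) biopsy
        start = "no_cancer"
        upfront = params.cost_mrm + params.cost_biopsy
        upfront_utility = -params.qaly_loss_biopsy

    spec = MarkovSpec(
        states=STATES,
        transitions=transitions,
        state_costs=state_costs,
        state_utilities=np.array(
            [params.utility_no_tumor, params.utility_tumor,
             params.utility_tumor, params.utility_dead]
        ),
        transition_costs=transition_costs or None,
        dead_state="dead",
    )
    return BranchModel(
        branch=branch,
        spec=spec,
        start_state=start,
        upfront_cost=upfront,
        upfront_utility_adjustment=upfront_utility,
    )


def evaluate_branch(
    branch: str,
    params: TKParameters,
    conventions: Conventions = Conventions(),
    return_trace: bool = False,
) -> BranchResult | tuple[BranchResult, CohortResult]:
    """Run the cohort model of one branch over the configured horizon."""
    model = build_branch(branch, params, conventions)
    result = run_cohort(
        model.spec,
        model.start_state,
        n_cycles=params.horizon,
        discount=DiscountSpec(params.discount_rate, conventions.discount_timing),
        upfront_cost=model.upfront_cost,
        upfront_utility_adjustment=model.upfront_utility_adjustment,
        half_cycle_correction=conventions.half_cycle_correction,
    )
    branch_result = BranchResult(
        branch=branch,
        expected_cost=result.expected_cost,
        expected_qalys=result.expected_qalys,
    )
    if return_trace:
        return branch_result, result
    return branch_result


def evaluate_all_branches(
    params: TKParameters,
    conventions: Conventions = Conventions(),
) -> dict[str, BranchResult]:
    """Expected 5-year discounted cost and QALYs for all four branches.

    Full precision is retained; rounding to two decimals is a reporting
    concern.
    """
    return {b: evaluate_branch(b, params, conventions) for b in BRANCHES}


@dataclass
class CalibrationResult:
    """Outcome of the convention grid search against reference branch values."""

    best: Conventions
    best_results: dict[str, BranchResult]
    residuals: pd.DataFrame
    grid_report: pd.DataFrame
    summed_relative_error: float

    @property
    def max_branch_relative_error(self) -> float:
        return float(
            self.residuals[["rel_err_cost", "rel_err_qalys"]].abs().max().max()
        )


def _as_reference(reference) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for branch in BRANCHES:
        ref = reference[branch]
        if isinstance(ref, BranchResult):
            out[branch] = (ref.expected_cost, ref.expected_qalys)
        else:
            cost, qalys = ref
            out[branch] = (float(cost), float(qalys))
    return out


def calibrate_conventions(
    params: TKParameters,
    reference: Mapping[str, BranchResult] | Mapping[str, tuple[float, float]],
) -> CalibrationResult:
    """Search the convention grid for the setting closest to reference values.

    The published evaluation was built in commercial decision-tree software
    whose cycle-reward and discount-timing settings are not documented, so
    per-branch expected values can only be reproduced up to these discrete
    conventions.  This exhaustively evaluates every candidate in
    :meth:`Conventions.grid` and minimises the summed relative error over
    the four branches (costs and QALYs together).

    Always returns the best setting found, with per-branch residuals and
    the full grid report; it never asserts a fit quality.
    """
    ref = _as_reference(reference)
    rows = []
    best: Conventions | None = None
    best_error = np.inf
    best_results: dict[str, BranchResult] | None = None
    for candidate in Conventions.grid():
        results = evaluate_all_branches(params, candidate)
        # FP is defined as TN plus the biopsy: this algebraic identity must
        # hold under every candidate setting.
        fp, tn = results["FP"], results["TN"]
        cost_gap = fp.expected_cost - tn.expected_cost
        qaly_gap = fp.expected_qalys - tn.expected_qalys
        if abs(cost_gap - params.cost_biopsy) > 1e-9 or (
            abs(qaly_gap + params.qaly_loss_biopsy) > 1e-9
        ):
            raise AssertionError(
                f"FP/TN identity violated under {candidate}: "
                f"cost gap {cost_gap}, QALY gap {qaly_gap}"
            )
        error = 0.0
        for branch in BRANCHES:
            ref_cost, ref_qalys = ref[branch]
            res = results[branch]
            error += abs(res.expected_cost - ref_cost) / abs(ref_cost)
            error += abs(res.expected_qalys - ref_qalys) / abs(ref_qalys)
        rows.append({**candidate.as_dict(), "summed_relative_error": error})
        if error < best_error - 1e-15:
            best_error = error
            best = candidate
            best_results = results

    assert best is not None and best_results is not None
    residuals = pd.DataFrame(
        [
            {
                "branch": branch,
                "cost_model": best_results[branch].expected_cost,
                "cost_reference": ref[branch][0],
                "rel_err_cost": (
                    best_results[branch].expected_cost - ref[branch][0]
                ) / ref[branch][0],
                "qalys_model": best_results[branch].expected_qalys,
                "qalys_reference": ref[branch][1],
                "rel_err_qalys": (
                    best_results[branch].expected_qalys - ref[branch][1]
                ) / ref[branch][1],
            }
            for branch in BRANCHES
        ]
    )
    grid_report = pd.DataFrame(rows).sort_values(
        "summed_relative_error", kind="stable"
    ).reset_index(drop=True)
    return CalibrationResult(
        best=best,
        best_results=best_results,
        residuals=residuals,
        grid_report=grid_report,
        summed_relative_error=best_error,
    )
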