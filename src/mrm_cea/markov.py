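"""Discrete-time Markov cohort engine with discounting and reward accrual.

A cohort model propagates a probability distribution over health states
through a sequence of row-stochastic transition matrices and accrues
per-cycle costs (currency) and utilities (QALY weights), discounted to
present value.  One state is absorbing ("dead" by default) with zero
utility.

Discounting conventions
-----------------------
``begin``
    Cycle ``t`` is discounted by ``(1+r)^-t`` and rewards use the state
    occupancy at the *start* of the cycle (cycle 0 undiscounted).
``end``
    Cycle ``t`` is discounted by ``(1+r)^-(t+1)`` and rewards use the
    occupancy at the *end* of the cycle.
``half``
    Cycle ``t`` is discounted by ``(1+r)^-(t+0.5)`` and rewards use the
    average of start- and end-of-cycle occupancy (half-cycle correction).

Independently of the convention, ``half_cycle_correction=True`` forces the
averaged occupancy while keeping the convention's discount exponent.
One-time transition costs are charged in the cycle the transition occurs,
using that cycle's discount factor.  Upfront (cycle-0, acute) costs and
one-time utility adjustments are passed to :func:`run_cohort` directly and
are never discounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONVENTIONS",
    "DiscountSpec",
    "discount_factor",
    "MarkovSpec",
    "CohortTrace",
    "CohortResult",
    "run_cohort",
]

CONVENTIONS = ("begin", "end", "half")

#: Row-sum tolerance for transition matrices.
_ROW_TOL = 1e-9


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate and timing convention."""

    annual_rate: float = 0.03
    convention: str = "begin"

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError(f"discount rate must be >= 0, got {self.annual_rate}")
        if self.convention not in CONVENTIONS:
            raise ValueError(
                f"convention must be one of {CONVENTIONS}, got {self.convention!r}"
            )


def discount_factor(rate: float, cycle: int, convention: str = "begin") -> float:
    """Present-value factor for a given cycle under a timing convention."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if cycle < 0:
        raise ValueError(f"cycle must be >= 0, got {cycle}")
    if convention == "begin":
        exponent = cycle
    elif convention == "end":
        exponent = cycle + 1
    elif convention == "half":
        exponent = cycle + 0.5
    else:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")
    return float((1.0 + rate) ** (-exponent))


@dataclass
class MarkovSpec:
    """A Markov cohort model: states, transitions and per-state rewards.

    Parameters
    ----------
    states
        Ordered state labels; must contain ``dead_state`` exactly once.
    transitions
        Callable mapping a cycle index to a row-stochastic matrix of shape
        ``(n_states, n_states)``.  Age dependence is expressed by closing
        over a start age (age = start_age + cycle for yearly cycles).
    state_costs
        Per-state cost accrued per cycle (currency units), either a fixed
        vector or a callable of the cycle index (for scheduled costs such
        as surveillance imaging in selected years).
    state_utilities
        Per-state utility weight per cycle, each in [0, 1]; the dead state
        must have utility 0.
    transition_costs
        Optional mapping ``(from_state, to_state) -> cost`` charged once per
        transition event, in the cycle the transition occurs.
    """

    states: Sequence[str]
    transitions: Callable[[int], np.ndarray]
    state_costs: np.ndarray | Sequence[float] | Callable[[int], np.ndarray]
    state_utilities: np.ndarray | Sequence[float]
    transition_costs: Mapping[tuple[str, str], float] | None = None
    dead_state: str = "dead"

    _utilities: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        if self.states.count(self.dead_state) != 1:
            raise ValueError(
                f"states must contain exactly one {self.dead_state!r} state"
            )
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")
        self._utilities = np.asarray(self.state_utilities, dtype=float)
        if self._utilities.shape != (len(self.states),):
            raise ValueError("state_utilities must have one entry per state")
        if np.any(self._utilities < 0) or np.any(self._utilities > 1):
            raise ValueError("state utilities must lie in [0, 1]")
        if self._utilities[self.dead_index] != 0.0:
            raise ValueError(f"utility of {self.dead_state!r} must be 0")
        if self.transition_costs:
            for frm, to in self.transition_costs:
                if frm not in self.states or to not in self.states:
                    raise ValueError(f"unknown states in transition cost ({frm}, {to})")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def dead_index(self) -> int:
        return self.states.index(self.dead_state)

    def state_index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise ValueError(f"unknown state {label!r}; states are {self.states}")

    def costs_at(self, cycle: int) -> np.ndarray:
        if callable(self.state_costs):
            costs = np.asarray(self.state_costs(cycle), dtype=float)
        else:
            costs = np.asarray(self.state_costs, dtype=float)
        if costs.shape != (self.n_states,):
            raise ValueError("state_costs must have one entry per state")
        if np.any(costs < 0):
            raise ValueError("state costs must be non-negative")
        return costs

    def matrix_at(self, cycle: int) -> np.ndarray:
        """Transition matrix for one cycle, validated."""
        mat = np.asarray(self.transitions(cycle), dtype=float)
        if mat.shape != (self.n_states, self.n_states):
            raise ValueError(
                f"transition matrix at cycle {cycle} has shape {mat.shape}, "
                f"expected ({self.n_states}, {self.n_states})"
            )
        for i, row in enumerate(mat):
            if np.any(row < -1e-15) or np.any(row > 1 + 1e-12):
                raise ValueError(
                    f"cycle {cycle}: transition row for state "
                    f"{self.states[i]!r} has entries outside [0, 1]: {row}"
                )
            if abs(row.sum() - 1.0) > _ROW_TOL:
                raise ValueError(
                    f"cycle {cycle}: transition row for state "
                    f"{self.states[i]!r} sums to {row.sum()!r}, not 1"
                )
        dead = self.dead_index
        expected = np.zeros(self.n_states)
        expected[dead] = 1.0
        if not np.allclose(mat[dead], expected, atol=_ROW_TOL):
            raise ValueError(
                f"cycle {cycle}: {self.dead_state!r} must be absorbing "
                f"(identity row), got {mat[dead]}"
            )
        return np.clip(mat, 0.0, 1.0)

    def transition_cost_matrix(self) -> np.ndarray:
        mat = np.zeros((self.n_states, self.n_states))
        if self.transition_costs:
            for (frm, to), cost in self.transition_costs.items():
                mat[self.state_index(frm), self.state_index(to)] = cost
        return mat


@dataclass
class CohortTrace:
    """Audit trail of a cohort run.

    ``occupancy`` has ``n_cycles + 1`` rows (start of each cycle plus the
    final distribution); ``disc_cost`` / ``disc_qalys`` hold the discounted
    accrual of each cycle (upfront amounts excluded).
    """

    states: tuple[str, ...]
    occupancy: np.ndarray
    disc_cost: np.ndarray
    disc_qalys: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = self.occupancy.shape[0]
        frame = pd.DataFrame(self.occupancy, columns=list(self.states))
        frame.insert(0, "cycle", np.arange(n))
        frame["disc_cost"] = np.concatenate([self.disc_cost, [np.nan]])
        frame["disc_qalys"] = np.concatenate([self.disc_qalys, [np.nan]])
        return frame


class CohortResult(NamedTuple):
    expected_cost: float
    expected_qalys: float
    trace: CohortTrace


def _reward_occupancy(
    convention: str, half_cycle_correction: bool, occ_start: np.ndarray,
    occ_end: np.ndarray,
) -> np.ndarray:
    if convention == "half" or half_cycle_correction:
        return 0.5 * (occ_start + occ_end)
    if convention == "end":
        return occ_end
    return occ_start


def run_cohort(
    spec: MarkovSpec,
    start_state: str,
    n_cycles: int,
    discount: DiscountSpec = DiscountSpec(),
    upfront_cost: float = 0.0,
    upfront_utility_adjustment: float = 0.0,
    half_cycle_correction: bool = False,
) -> CohortResult:
    """Propagate a cohort and accrue discounted costs and QALYs.

    Parameters
    ----------
    spec
        Validated model structure.
    start_state
        State holding the whole cohort at cycle 0.
    n_cycles
        Number of one-year cycles (the model horizon).
    discount
        Rate and timing convention (see module docstring).
    upfront_cost, upfront_utility_adjustment
        One-time, undiscounted amounts added to the totals (acute costs of
        the diagnostic work-up; one-time utility decrements).
    half_cycle_correction
        Average start/end occupancy for reward accrual regardless of the
        discount convention.

    Returns
    -------
    CohortResult
        Expected discounted cost, expected discounted QALYs and the
        per-cycle trace.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    start = spec.state_index(start_state)

    occupancy = np.zeros((n_cycles + 1, spec.n_states))
    occupancy[0, start] = 1.0
    disc_cost = np.zeros(n_cycles)
    disc_qalys = np.zeros(n_cycles)
    trans_cost_mat = spec.transition_cost_matrix()
    has_trans_costs = bool(np.any(trans_cost_mat))

    for t in range(n_cycles):
        mat = spec.matrix_at(t)
        occupancy[t + 1] = occupancy[t] @ mat
        factor = discount_factor(discount.annual_rate, t, discount.convention)
        weights = _reward_occupancy(
            discount.convention, half_cycle_correction, occupancy[t], occupancy[t + 1]
        )
        cycle_cost = float(weights @ spec.costs_at(t))
        if has_trans_costs:
            flows = occupancy[t][:, None] * mat
            cycle_cost += float((flows * trans_cost_mat).sum())
        disc_cost[t] = factor * cycle_cost
        disc_qalys[t] = factor * float(weights @ spec._utilities)

    trace = CohortTrace(
        states=tuple(spec.states),
        occupancy=occupancy,
        disc_cost=disc_cost,
        disc_qalys=disc_qalys,
    )
    return CohortResult(
        expected_cost=upfront_cost + float(disc_cost.sum()),
        expected_qalys=upfront_utility_adjustment + float(disc_qalys.sum()),
        trace=trace,
    )
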