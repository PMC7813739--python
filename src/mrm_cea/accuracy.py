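"""Diagnostic test performance and decision-tree branch probabilities.

A screening test applied to a cohort yields a 2x2 confusion table
(TP/FP/TN/FN against ground truth).  This module computes the standard
performance metrics from such a table, converts test performance plus
disease prevalence into the four branch probabilities of a diagnostic
decision tree, and samples synthetic confusion tables for a cohort of a
given size.

Metrics are kept as exact fractions; any rounding to percentages happens
only in the reporting layer.  A metric whose denominator is zero (e.g.
sensitivity in a cohort with no diseased patients) is carried as an
explicit ``None`` together with a warning, never as a silent zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "DiagnosticPerformance",
    "BranchProbabilities",
    "compute_performance",
    "branch_probabilities",
    "sample_confusion",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a 2x2 diagnostic confusion table."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def scaled(self, k: int) -> "ConfusionCounts":
        """Return the table with every cell multiplied by ``k``."""
        return ConfusionCounts(self.tp * k, self.fp * k, self.tn * k, self.fn * k)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Standard diagnostic metrics, each a proportion in [0, 1] or ``None``.

    ``None`` marks a metric that is undefined for the given table because
    its denominator is zero.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    prevalence: float

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "prevalence": self.prevalence,
        }


@dataclass(frozen=True)
class BranchProbabilities:
    """Probabilities of the four diagnostic decision-tree branches.

    p_tp = prevalence * sensitivity
    p_fn = prevalence * (1 - sensitivity)
    p_tn = (1 - prevalence) * specificity
    p_fp = (1 - prevalence) * (1 - specificity)

    These sum to 1 by construction.
    """

    p_tp: float
    p_fn: float
    p_tn: float
    p_fp: float

    def __post_init__(self) -> None:
        for name, p in self.as_dict().items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if abs(sum(self.as_dict().values()) - 1.0) > 1e-12:
            raise ValueError("branch probabilities must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.p_tp,
            "FN": self.p_fn,
            "TN": self.p_tn,
            "FP": self.p_fp,
        }


def _ratio(num: int, den: int, metric: str) -> float | None:
    if den == 0:
        warnings.warn(
            f"{metric} is undefined: denominator is zero", RuntimeWarning, stacklevel=3
        )
        return None
    return num / den


def compute_performance(counts: ConfusionCounts) -> DiagnosticPerformance:
    """Compute sensitivity, specificity, PPV, NPV, accuracy and prevalence.

    Parameters
    ----------
    counts
        Confusion table with ``total > 0``.

    Returns
    -------
    DiagnosticPerformance
        Exact fractions; metrics with zero denominators are ``None`` and a
        ``RuntimeWarning`` is emitted for each.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from an empty confusion table")
    return DiagnosticPerformance(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        specificity=_ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        ppv=_ratio(counts.tp, counts.tp + counts.fp, "ppv"),
        npv=_ratio(counts.tn, counts.tn + counts.fn, "npv"),
        accuracy=(counts.tp + counts.tn) / counts.total,
        prevalence=(counts.tp + counts.fn) / counts.total,
    )


def _check_proportion(name: str, value: float) -> None:
    if not (isinstance(value, (int, float, np.floating, np.integer))
            and math.isfinite(value)):
        raise ValueError(f"{name} must be a finite number, got {value!r}")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def branch_probabilities(
    prevalence: float, sensitivity: float, specificity: float
) -> BranchProbabilities:
    """Convert prevalence and test performance into decision-tree branch
    probabilities.

    The pre-test probability of disease splits the cohort; sensitivity and
    specificity then split each arm into correct and incorrect test results.
    """
    _check_proportion("prevalence", prevalence)
    _check_proportion("sensitivity", sensitivity)
    _check_proportion("specificity", specificity)
    return BranchProbabilities(
        p_tp=prevalence * sensitivity,
        p_fn=prevalence * (1.0 - sensitivity),
        p_tn=(1.0 - prevalence) * specificity,
        p_fp=(1.0 - prevalence) * (1.0 - specificity),
    )


def sample_confusion(
    n: int,
    prevalence: float,
    sensitivity: float,
    specificity: float,
    seed: int | np.random.Generator | None = None,
) -> ConfusionCounts:
    """Draw a synthetic confusion table for a screening cohort of size ``n``.

    Each patient's disease status is Bernoulli(prevalence); the test result
    is then Bernoulli(sensitivity) for diseased and Bernoulli(specificity)
    for healthy patients.  Reproducible under a fixed seed.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    _check_proportion("prevalence", prevalence)
    _check_proportion("sensitivity", sensitivity)
    _check_proportion("specificity", specificity)
    rng = np.random.default_rng(seed)
    diseased = int(rng.binomial(n, prevalence))
    healthy = n - diseased
    tp = int(rng.binomial(diseased, sensitivity))
    tn = int(rng.binomial(healthy, specificity))
    return ConfusionCounts(tp=tp, fp=healthy - tn, tn=tn, fn=diseased - tp)
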