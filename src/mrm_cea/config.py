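"""Run configuration: YAML loading, validation and round-tripping.

A run is configured by a single YAML file with the sections ``params``
(model inputs, keys matching :class:`~mrm_cea.model.TKParameters` fields),
``conventions`` (engine knobs), ``dsa``, ``microsim``, and optionally
``accuracy_counts`` (a confusion table to push through the accuracy
stage).  An empty or missing file yields the study defaults.  Unknown keys
are rejected by name rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .accuracy import ConfusionCounts
from .model import Conventions, TKParameters

__all__ = [
    "DSAConfig",
    "MicrosimConfig",
    "RunConfig",
    "load_config",
    "dump_config",
    "load_background_mortality",
]

_DEFAULT_DSA_RANGES: dict[str, tuple[float, float]] = {
    "prevalence": (0.0, 0.20),
    "sensitivity_mrm": (0.70, 1.00),
    "specificity_mrm": (0.70, 1.00),
}


@dataclass(frozen=True)
class DSAConfig:
    """One-way sensitivity-analysis settings."""

    mode: str = "branch-values"
    n_points: int = 21
    #: Branch values used in branch-values mode: the published reference
    #: results ("reported") or this package's own Markov output ("model").
    branch_values_source: str = "reported"
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DSA_RANGES)
    )

    def __post_init__(self) -> None:
        if self.mode not in ("branch-values", "full-model"):
            raise ValueError(f"dsa.mode must be branch-values or full-model")
        if self.branch_values_source not in ("reported", "model"):
            raise ValueError(
                "dsa.branch_values_source must be 'reported' or 'model'"
            )
        if self.n_points < 1:
            raise ValueError("dsa.n_points must be >= 1")
        normalized = {}
        for name, bounds in self.ranges.items():
            low, high = bounds
            normalized[name] = (float(low), float(high))
        object.__setattr__(self, "ranges", normalized)


@dataclass(frozen=True)
class MicrosimConfig:
    """Patient-level simulation settings."""

    enabled: bool = False
    n: int = 100_000
    seed: int = 12345
    collect_trajectories: bool = False
    max_trajectories: int = 10_000

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("microsim.n must be >= 1")
        if self.max_trajectories < 0:
            raise ValueError("microsim.max_trajectories must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    params: TKParameters = field(default_factory=TKParameters)
    conventions: Conventions = field(default_factory=Conventions)
    dsa: DSAConfig = field(default_factory=DSAConfig)
    microsim: MicrosimConfig = field(default_factory=MicrosimConfig)
    accuracy_counts: ConfusionCounts | None = None
    report_decimals: int = 2

    def __post_init__(self) -> None:
        if self.report_decimals < 0:
            raise ValueError("report_decimals must be >= 0")


def _check_keys(section: str, data: Mapping[str, Any], allowed: set[str]) -> None:
    unknown = sorted(set(data) - allowed)
    if unknown:
        where = f" in section {section!r}" if section else ""
        raise ValueError(f"unknown configuration key(s){where}: {unknown}")


def _build_params(data: Mapping[str, Any]) -> TKParameters:
    allowed = {f.name for f in fields(TKParameters)}
    _check_keys("params", data, allowed)
    kwargs = dict(data)
    if "p_death_background" in kwargs:
        kwargs["p_death_background"] = {
            int(age): float(p) for age, p in kwargs["p_death_background"].items()
        }
    return TKParameters(**kwargs)


def _build_section(section: str, data: Mapping[str, Any], cls):
    allowed = {f.name for f in fields(cls)}
    _check_keys(section, data, allowed)
    if section == "dsa" and "ranges" in data:
        data = dict(data)
        data["ranges"] = {
            name: tuple(bounds) for name, bounds in data["ranges"].items()
        }
    return cls(**data)


def load_config(
    path: str | Path | None = None,
    background_mortality_csv: str | Path | None = None,
) -> RunConfig:
    """Load and validate a run configuration.

    ``path=None`` returns the study defaults.  ``background_mortality_csv``
    optionally overrides the per-age background-mortality table (columns:
    ``age``, ``annual_death_probability``).
    """
    raw: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"configuration file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("configuration root must be a mapping")
        raw = loaded

    _check_keys(
        "", raw,
        {"params", "conventions", "dsa", "microsim", "accuracy_counts",
         "report_decimals"},
    )
    params = _build_params(raw.get("params", {}))
    if background_mortality_csv is not None:
        params = params.with_overrides(
            p_death_background=load_background_mortality(background_mortality_csv)
        )
    conventions = _build_section(
        "conventions", raw.get("conventions", {}), Conventions
    )
    dsa = _build_section("dsa", raw.get("dsa", {}), DSAConfig)
    microsim = _build_section("microsim", raw.get("microsim", {}), MicrosimConfig)
    counts = None
    if "accuracy_counts" in raw and raw["accuracy_counts"] is not None:
        data = raw["accuracy_counts"]
        _check_keys("accuracy_counts", data, {"tp", "fp", "tn", "fn"})
        counts = ConfusionCounts(**{k: int(v) for k, v in data.items()})
    return RunConfig(
        params=params,
        conventions=conventions,
        dsa=dsa,
        microsim=microsim,
        accuracy_counts=counts,
        report_decimals=int(raw.get("report_decimals", 2)),
    )


def dump_config(config: RunConfig) -> str:
    """Serialise a configuration to YAML that round-trips via
    :func:`load_config`."""
    data: dict[str, Any] = {
        "params": {
            **{
                k: v
                for k, v in config.params.as_dict().items()
                if k not in ("p_death_background", "distribution_family")
            },
            "p_death_background": dict(config.params.p_death_background),
        },
        "conventions": config.conventions.as_dict(),
        "dsa": {
            "mode": config.dsa.mode,
            "n_points": config.dsa.n_points,
            "branch_values_source": config.dsa.branch_values_source,
            "ranges": {k: list(v) for k, v in config.dsa.ranges.items()},
        },
        "microsim": {
            "enabled": config.microsim.enabled,
            "n": config.microsim.n,
            "seed": config.microsim.seed,
            "collect_trajectories": config.microsim.collect_trajectories,
            "max_trajectories": config.microsim.max_trajectories,
        },
        "report_decimals": config.report_decimals,
    }
    if config.accuracy_counts is not None:
        c = config.accuracy_counts
        data["accuracy_counts"] = {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
    return yaml.safe_dump(data, sort_keys=True)


def load_background_mortality(path: str | Path) -> dict[int, float]:
    """Read a per-age annual background mortality table from CSV."""
    frame = pd.read_csv(path)
    required = {"age", "annual_death_probability"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"background mortality CSV must have columns {sorted(required)}"
        )
    return {
        int(row.age): float(row.annual_death_probability)
        for row in frame.itertuples()
    }
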