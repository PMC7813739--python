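"""End-to-end pipeline: accuracy stage, branch models, base case, DSA,
calibration and (optionally) microsimulation, with CSV reporting.

Every report carries full-precision machine-readable columns; currency and
QALY columns rounded to the configured number of decimals are added with a
``_rounded`` suffix.  Outputs contain no timestamps, so a rerun with the
same configuration and seed is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import reference
from .accuracy import compute_performance
from .config import RunConfig
from .decision import base_case, one_way_dsa, qaly_gain, tornado_order, \
    tree_probabilities
from .microsim import simulate_cohort
from .model import BRANCHES, BranchResult, calibrate_conventions, \
    evaluate_all_branches

__all__ = ["run_pipeline"]

logger = logging.getLogger("mrm_cea")


def _round(frame: pd.DataFrame, columns: list[str], decimals: int) -> pd.DataFrame:
    for col in columns:
        if col in frame.columns:
            frame[f"{col}_rounded"] = frame[col].round(decimals)
    return frame


def _log_parameters(config: RunConfig) -> pd.DataFrame:
    rows = []
    for name, value in config.params.as_dict().items():
        if name in ("p_death_background", "distribution_family"):
            value = repr(dict(value))
        rows.append({"section": "params", "name": name, "value": value})
        logger.info("parameter params.%s = %s", name, value)
    for name, value in config.conventions.as_dict().items():
        rows.append({"section": "conventions", "name": name, "value": value})
        logger.info("parameter conventions.%s = %s", name, value)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Run every configured stage and write one CSV per report.

    Returns the written tables keyed by report name (file stem).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    decimals = config.report_decimals
    reports: dict[str, pd.DataFrame] = {}

    reports["parameters_used"] = _log_parameters(config)

    if config.accuracy_counts is not None:
        perf = compute_performance(config.accuracy_counts)
        counts = config.accuracy_counts
        row = {
            "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
            **perf.as_dict(),
        }
        reports["accuracy"] = pd.DataFrame([row])
        logger.info("accuracy stage: %s", row)

    logger.info("evaluating branch models under %s", config.conventions)
    branch_results = evaluate_all_branches(config.params, config.conventions)
    reports["branch_results"] = _round(
        pd.DataFrame(
            [
                {
                    "branch": b,
                    "expected_cost": branch_results[b].expected_cost,
                    "expected_qalys": branch_results[b].expected_qalys,
                }
                for b in BRANCHES
            ]
        ),
        ["expected_cost", "expected_qalys"],
        decimals,
    )

    probs = tree_probabilities(config.params)
    rows = []
    for source, results in (
        ("model", branch_results),
        ("reported", reference.REPORTED_BRANCH_RESULTS),
    ):
        bc = base_case(results, probs, config.params.wtp)
        rows.append(
            {
                "branch_values_source": source,
                "expected_cost": bc.expected_cost,
                "expected_qalys": bc.expected_qalys,
                "nmb": bc.nmb,
                "wtp": bc.wtp,
                "qaly_gain_tp_vs_fn": qaly_gain(results, "TP", "FN"),
            }
        )
    reports["base_case"] = _round(
        pd.DataFrame(rows),
        ["expected_cost", "expected_qalys", "nmb", "qaly_gain_tp_vs_fn"],
        decimals,
    )
    logger.info("base case: %s", rows)

    dsa_branch_values: Mapping[str, BranchResult] | None = None
    if config.dsa.mode == "branch-values":
        dsa_branch_values = (
            reference.REPORTED_BRANCH_RESULTS
            if config.dsa.branch_values_source == "reported"
            else branch_results
        )
    dsa = one_way_dsa(
        config.params,
        config.dsa.ranges,
        n_points=config.dsa.n_points,
        mode=config.dsa.mode,
        branch_results=dsa_branch_values,
        conventions=config.conventions,
    )
    reports["dsa"] = _round(
        tornado_order(dsa),
        ["cost_low", "cost_high", "cost_min", "cost_max",
         "qaly_min", "qaly_max", "swing"],
        decimals,
    )

    calibration = calibrate_conventions(
        config.params, reference.REPORTED_BRANCH_RESULTS
    )
    best = pd.DataFrame([calibration.best.as_dict()])
    best["summed_relative_error"] = calibration.summed_relative_error
    reports["calibration_best_setting"] = best
    reports["calibration_residuals"] = calibration.residuals
    logger.info(
        "calibration best setting %s (summed relative error %.4f)",
        calibration.best, calibration.summed_relative_error,
    )

    if config.microsim.enabled:
        logger.info(
            "microsimulation: n=%d seed=%d",
            config.microsim.n, config.microsim.seed,
        )
        summary = simulate_cohort(
            config.params,
            config.conventions,
            n=config.microsim.n,
            seed=config.microsim.seed,
            collect_trajectories=config.microsim.collect_trajectories,
            max_trajectories=config.microsim.max_trajectories,
        )
        reports["microsim_summary"] = summary.table
        if summary.trajectories is not None:
            reports["microsim_trajectories"] = summary.trajectories

    for name, frame in reports.items():
        target = outdir / f"{name}.csv"
        frame.to_csv(target, index=False)
        logger.info("wrote %s", target)
    return reports
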