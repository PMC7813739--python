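"""Branch model construction, evaluation and convention calibration."""

import numpy as np
import pytest

from mrm_cea.model import (
    BRANCHES,
    Conventions,
    TKParameters,
    build_branch,
    calibrate_conventions,
    evaluate_all_branches,
    evaluate_branch,
)
from mrm_cea.reference import REPORTED_BRANCH_RESULTS

FULL_HEALTH_5Y = sum(1.03 ** -t for t in range(5))


def painless_params(**overrides) -> TKParameters:
    """Degenerate parameters: no costs, full utility, no mortality."""
    base = dict(
        cost_mrm=0.0, cost_biopsy=0.0, cost_early_surgery=0.0,
        cost_delayed_surgery=0.0, yearly_cost_tumor=0.0,
        utility_tumor=1.0, qaly_loss_biopsy=0.0,
        p_death_tumor=0.0, p_death_background={32: 0.0},
    )
    base.update(overrides)
    return TKParameters(**base)


class TestParameters:
    def test_defaults_are_the_study_inputs(self):
        p = TKParameters()
        assert p.discount_rate == 0.03
        assert p.cost_mrm == 418.50
        assert p.utility_tumor == 0.7
        assert p.p_death_tumor == 0.0544
        assert p.horizon == 5
        assert p.wtp == 100_000.0
        assert p.distribution_family["cost_mrm"] == "gamma"
        assert p.distribution_family["prevalence"] == "beta"

    @pytest.mark.parametrize(
        "overrides",
        [
            {"prevalence": 1.5},
            {"cost_mrm": -1.0},
            {"utility_dead": 0.5},
            {"horizon": 0},
            {"p_treatment_success": 0.99, "p_death_tumor": 0.2},
            {"p_death_background": {}},
        ],
    )
    def test_domain_violations_rejected(self, overrides):
        with pytest.raises(ValueError):
            TKParameters(**overrides)

    def test_background_mortality_clamped_to_table(self):
        p = TKParameters(p_death_background={30: 0.001, 40: 0.002})
        assert p.background_mortality_at(30) == 0.001
        assert p.background_mortality_at(25) == 0.001
        assert p.background_mortality_at(35) == 0.001
        assert p.background_mortality_at(99) == 0.002


class TestBuildBranch:
    def test_upfront_costs_and_start_states(self, params):
        tp = build_branch("TP", params)
        assert tp.start_state == "no_cancer"
        assert tp.upfront_cost == pytest.approx(418.50 + 300.0 + 4000.0)
        fn = build_branch("FN", params)
        assert fn.start_state == "cancer_untreated"
        assert fn.upfront_cost == pytest.approx(418.50)
        tn = build_branch("TN", params)
        assert tn.upfront_cost == pytest.approx(418.50)
        fp = build_branch("FP", params)
        assert fp.upfront_cost == pytest.approx(418.50 + 300.0)
        assert fp.upfront_utility_adjustment == pytest.approx(-0.05)

    def test_fn_surgery_timing_moves_the_delayed_cost(self, params):
        on_success = build_branch("FN", params, Conventions())
        assert on_success.spec.transition_costs[
            ("cancer_untreated", "no_cancer")
        ] == pytest.approx(10_000.0)
        upfront = build_branch(
            "FN", params, Conventions(fn_surgery_timing="upfront")
        )
        assert upfront.upfront_cost == pytest.approx(418.50 + 10_000.0)
        assert ("cancer_untreated", "no_cancer") not in (
            upfront.spec.transition_costs or {}
        )

    def test_fn_cancer_row(self, params):
        """The untreated-cancer row is success/stay/death and sums to 1."""
        model = build_branch("FN", params)
        matrix = model.spec.matrix_at(0)
        row = matrix[model.spec.state_index("cancer_untreated")]
        assert row[model.spec.state_index("no_cancer")] == pytest.approx(0.60)
        assert row[model.spec.state_index("dead")] == pytest.approx(0.0544)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_branch_rejected(self, params):
        with pytest.raises(ValueError, match="unknown branch"):
            build_branch("XX", params)

    def test_recurrence_only_for_treated_cancer_by_default(self, params):
        tn = build_branch("TN", params)
        row = tn.spec.matrix_at(0)[tn.spec.state_index("no_cancer")]
        assert row[tn.spec.state_index("cancer_recurrent")] == 0.0
        tp = build_branch("TP", params)
        row = tp.spec.matrix_at(0)[tp.spec.state_index("no_cancer")]
        assert row[tp.spec.state_index("cancer_recurrent")] == pytest.approx(0.045)


class TestEvaluateBranches:
    def test_fp_minus_tn_is_exactly_the_biopsy_under_every_convention(
        self, params
    ):
        for conventions in Conventions.grid():
            results = evaluate_all_branches(params, conventions)
            cost_gap = results["FP"].expected_cost - results["TN"].expected_cost
            qaly_gap = results["FP"].expected_qalys - results["TN"].expected_qalys
            assert cost_gap == pytest.approx(params.cost_biopsy, abs=1e-9)
            assert qaly_gap == pytest.approx(-params.qaly_loss_biopsy, abs=1e-9)

    def test_degenerate_parameters_give_zero_cost_full_health(self):
        results = evaluate_all_branches(painless_params())
        for branch in BRANCHES:
            assert results[branch].expected_cost == pytest.approx(0.0, abs=1e-9)
            assert results[branch].expected_qalys == pytest.approx(
                FULL_HEALTH_5Y, abs=1e-9
            )

    @pytest.mark.parametrize(
        "overrides",
        [
            {},
            {"yearly_cost_tumor": 20_000.0},
            {"utility_tumor": 0.5},
            {"p_death_tumor": 0.2, "p_treatment_success": 0.5},
        ],
    )
    def test_timely_diagnosis_dominates_delayed(self, overrides):
        """TP costs less and yields more QALYs than FN whenever delayed
        surgery is at least as expensive and cancer mortality is positive."""
        p = TKParameters(**overrides)
        for conventions in (
            Conventions(),
            Conventions(discount_timing="end", fn_surgery_timing="upfront"),
        ):
            results = evaluate_all_branches(p, conventions)
            assert results["TP"].expected_cost < results["FN"].expected_cost
            assert results["TP"].expected_qalys > results["FN"].expected_qalys

    def test_qalys_bounded_by_discounted_full_health(self, params):
        results = evaluate_all_branches(params)
        for branch in BRANCHES:
            assert results[branch].expected_qalys <= FULL_HEALTH_5Y + 1e-12

    def test_tumor_cost_moves_fn_not_tn(self, params):
        base = evaluate_all_branches(params)
        costly = evaluate_all_branches(
            params.with_overrides(yearly_cost_tumor=30_000.0)
        )
        assert costly["FN"].expected_cost > base["FN"].expected_cost
        assert costly["TN"].expected_cost == pytest.approx(
            base["TN"].expected_cost, abs=1e-9
        )

    def test_horizon_sets_cycle_count(self, params):
        _, cohort = evaluate_branch("TN", params, return_trace=True)
        assert cohort.trace.occupancy.shape[0] == params.horizon + 1


class TestCalibration:
    def test_roundtrip_recovers_known_setting(self, params):
        """Calibrating against the model's own output under a known setting
        finds that setting with (numerically) zero residual."""
        known = Conventions(
            discount_timing="end",
            half_cycle_correction=True,
            recurrence_tn_fp=True,
            recurrence_event_cost="delayed",
            surveillance="annual",
            fn_surgery_timing="on_success",
        )
        reference = evaluate_all_branches(params, known)
        result = calibrate_conventions(params, reference)
        assert result.best == known
        assert result.summed_relative_error == pytest.approx(0.0, abs=1e-12)

    def test_reported_values_fit_within_five_percent(self, params):
        result = calibrate_conventions(params, REPORTED_BRANCH_RESULTS)
        assert len(result.grid_report) == 216
        assert set(result.residuals["branch"]) == set(BRANCHES)
        assert result.max_branch_relative_error <= 0.05
        assert np.isfinite(result.summed_relative_error)
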