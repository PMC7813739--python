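"""Decision-tree roll-back, NMB and one-way sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from mrm_cea.accuracy import BranchProbabilities, branch_probabilities
from mrm_cea.decision import (
    base_case,
    one_way_dsa,
    qaly_gain,
    tornado_order,
    tree_probabilities,
)
from mrm_cea.model import BranchResult, TKParameters
from mrm_cea.reference import (
    REPORTED_BRANCH_RESULTS,
    REPORTED_DSA_RANGES,
)


@pytest.fixture
def study_probs(params):
    return tree_probabilities(params)


class TestBaseCase:
    def test_reported_branch_values_reproduce_the_base_case(
        self, params, study_probs
    ):
        bc = base_case(REPORTED_BRANCH_RESULTS, study_probs, params.wtp)
        assert round(bc.expected_cost, 2) == 1650.48
        assert round(bc.expected_qalys, 2) == 4.69
        assert bc.nmb == pytest.approx(
            params.wtp * bc.expected_qalys - bc.expected_cost, abs=1e-9
        )
        assert bc.nmb > 0  # acceptable at the configured WTP

    def test_degenerate_tree_equals_single_branch(self, params):
        probs = BranchProbabilities(1.0, 0.0, 0.0, 0.0)
        bc = base_case(REPORTED_BRANCH_RESULTS, probs, params.wtp)
        assert bc.expected_cost == pytest.approx(7606.80)
        assert bc.expected_qalys == pytest.approx(4.62)

    def test_zero_costs_leave_nmb_as_valued_qalys(self, params, study_probs):
        free = {
            b: BranchResult(b, 0.0, r.expected_qalys)
            for b, r in REPORTED_BRANCH_RESULTS.items()
        }
        bc = base_case(free, study_probs, params.wtp)
        assert bc.expected_cost == 0.0
        assert bc.nmb == pytest.approx(params.wtp * bc.expected_qalys)

    def test_linearity_in_branch_costs(self, params, study_probs):
        scaled = {
            b: BranchResult(b, 3.0 * r.expected_cost, r.expected_qalys)
            for b, r in REPORTED_BRANCH_RESULTS.items()
        }
        bc = base_case(REPORTED_BRANCH_RESULTS, study_probs, params.wtp)
        bc3 = base_case(scaled, study_probs, params.wtp)
        assert bc3.expected_cost == pytest.approx(3.0 * bc.expected_cost, rel=1e-12)

    def test_missing_branch_rejected(self, params, study_probs):
        partial = {b: REPORTED_BRANCH_RESULTS[b] for b in ("TP", "FN", "TN")}
        with pytest.raises(ValueError, match="FP"):
            base_case(partial, study_probs, params.wtp)

    def test_probabilities_must_be_a_distribution(self):
        with pytest.raises(ValueError, match="sum"):
            BranchProbabilities(0.5, 0.1, 0.1, 0.1)


class TestQalyGain:
    def test_timely_versus_delayed_diagnosis(self):
        gain = qaly_gain(REPORTED_BRANCH_RESULTS, "TP", "FN")
        assert round(gain, 2) == 0.67

    def test_tn_versus_fp_is_the_biopsy_loss(self):
        assert qaly_gain(REPORTED_BRANCH_RESULTS, "TN", "FP") == pytest.approx(
            0.05
        )

    def test_self_difference_is_zero(self):
        assert qaly_gain(REPORTED_BRANCH_RESULTS, "TN", "TN") == 0.0

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValueError):
            qaly_gain(REPORTED_BRANCH_RESULTS, "TP", "XX")


class TestOneWayDSA:
    def test_printed_ranges_respect_cost_bound_and_qaly_window(self, params):
        """Over prevalence 0-20% and sens/spec 70-100% (one at a time, branch
        values fixed), costs stay below 2500 EUR and QALYs in [4.68, 4.70]."""
        dsa = one_way_dsa(
            params, REPORTED_DSA_RANGES,
            branch_results=REPORTED_BRANCH_RESULTS,
        )
        assert dsa["cost_max"].max() == pytest.approx(2483.088, abs=0.005)
        assert dsa["cost_max"].max() <= 2500.0
        assert round(dsa["qaly_min"].min(), 2) == 4.68
        assert round(dsa["qaly_max"].max(), 2) == 4.70

    def test_extremes_lie_at_endpoints_for_tree_parameters(self, params):
        dsa = one_way_dsa(
            params, REPORTED_DSA_RANGES,
            branch_results=REPORTED_BRANCH_RESULTS,
        )
        for _, row in dsa.iterrows():
            assert row["cost_max"] == pytest.approx(
                max(row["cost_low"], row["cost_high"]), abs=1e-9
            )
            assert row["qaly_min"] == pytest.approx(
                min(row["qaly_low"], row["qaly_high"]), abs=1e-9
            )

    def test_degenerate_range_is_a_single_point(self, params):
        dsa = one_way_dsa(
            params, {"prevalence": (0.07, 0.07)},
            branch_results=REPORTED_BRANCH_RESULTS,
        )
        row = dsa.iloc[0]
        bc = base_case(
            REPORTED_BRANCH_RESULTS, tree_probabilities(params), params.wtp
        )
        assert row["cost_low"] == pytest.approx(bc.expected_cost)
        assert row["swing"] == 0.0

    def test_out_of_domain_range_rejected(self, params):
        with pytest.raises(ValueError, match="domain"):
            one_way_dsa(
                params, {"prevalence": (0.0, 1.5)},
                branch_results=REPORTED_BRANCH_RESULTS,
            )

    def test_non_tree_parameter_needs_full_model_mode(self, params):
        with pytest.raises(ValueError, match="full-model"):
            one_way_dsa(
                params, {"cost_mrm": (200.0, 600.0)},
                branch_results=REPORTED_BRANCH_RESULTS,
            )
        full = one_way_dsa(
            params, {"cost_mrm": (200.0, 600.0)}, mode="full-model", n_points=5
        )
        assert full.iloc[0]["cost_high"] > full.iloc[0]["cost_low"]

    def test_cost_monotone_in_prevalence(self, params):
        """Diseased branches cost more, so expected cost rises with
        prevalence."""
        costs = []
        for prevalence in np.linspace(0, 0.2, 9):
            probs = branch_probabilities(prevalence, 1.0, 0.97)
            costs.append(
                base_case(REPORTED_BRANCH_RESULTS, probs, params.wtp).expected_cost
            )
        assert np.all(np.diff(costs) > 0)

    def test_qalys_monotone_in_sensitivity_and_specificity(self, params):
        for vary in ("sensitivity", "specificity"):
            qalys = []
            for level in np.linspace(0.7, 1.0, 7):
                probs = branch_probabilities(
                    0.07,
                    level if vary == "sensitivity" else 1.0,
                    level if vary == "specificity" else 0.97,
                )
                qalys.append(
                    base_case(
                        REPORTED_BRANCH_RESULTS, probs, params.wtp
                    ).expected_qalys
                )
            assert np.all(np.diff(qalys) > 0)


class TestTornadoOrder:
    def test_prevalence_outranks_mrm_price(self, params):
        """The pre-test probability drives costs harder than halving or
        adding half the MRM fee."""
        prevalence = one_way_dsa(
            params, {"prevalence": (0.0, 0.20)},
            branch_results=REPORTED_BRANCH_RESULTS,
        )
        mrm_price = one_way_dsa(
            params,
            {"cost_mrm": (418.50 * 0.5, 418.50 * 1.5)},
            mode="full-model", n_points=5,
        )
        combined = tornado_order(
            pd.concat([mrm_price, prevalence], ignore_index=True)
        )
        assert combined.iloc[0]["parameter"] == "prevalence"

    def test_single_row_table_is_itself(self, params):
        dsa = one_way_dsa(
            params, {"prevalence": (0.0, 0.2)},
            branch_results=REPORTED_BRANCH_RESULTS,
        )
        ordered = tornado_order(dsa)
        pd.testing.assert_frame_equal(ordered, dsa.reset_index(drop=True))

    def test_zero_swings_preserve_input_order(self, params):
        dsa = one_way_dsa(
            params,
            {
                "specificity_mrm": (0.97, 0.97),
                "sensitivity_mrm": (1.0, 1.0),
                "prevalence": (0.07, 0.07),
            },
            branch_results=REPORTED_BRANCH_RESULTS,
        )
        ordered = tornado_order(dsa)
        assert list(ordered["parameter"]) == [
            "specificity_mrm", "sensitivity_mrm", "prevalence",
        ]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            tornado_order(pd.DataFrame())
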