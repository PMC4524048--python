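"""Incremental analysis, dominance, NMB, one-way SA and scenarios."""
import copy
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pscea import (
    ArmResult,
    ValidationError,
    fit_parametric,
    format_incremental,
    get_parameter,
    incremental,
    nmb,
    one_way_sa,
    run_model,
    scenario_run,
    set_parameter,
    simulate_ipd,
    write_ipd,
)
from pscea.config import OwsaSpec
from pscea.synthetic import IpdSimSpec


def _result(arm_id, cost, qalys, lys=None):
    lys = qalys if lys is None else lys
    return ArmResult(
        arm_id=arm_id,
        cost_treatment_and_administration=cost,
        cost_adverse_events=0.0,
        cost_pre_progression_background=0.0,
        cost_post_progression_background=0.0,
        cost_terminal_care=0.0,
        qalys_pre=qalys,
        qalys_post=0.0,
        ly_pre_discounted=lys,
        ly_post_discounted=0.0,
        ly_pre_undiscounted=lys,
        ly_post_undiscounted=0.0,
    )


class TestIncremental:
    def test_cheaper_and_more_effective_dominates(self):
        inc = incremental(_result("a", 55022, 1.724), _result("b", 67980, 1.689))
        assert inc.label == "dominant"
        assert inc.quadrant == "SE"
        assert format_incremental(inc) == "Dominant"

    def test_cheaper_but_less_effective_is_southwest(self):
        inc = incremental(_result("a", 55022, 1.724, lys=3.043),
                          _result("b", 67980, 1.689, lys=3.082), measure="LY")
        assert inc.label == "less_effective_and_cheaper"
        assert inc.quadrant == "SW"
        assert inc.icer is not None and inc.icer > 0  # savings per LY forgone
        assert format_incremental(inc) == "Less effective"

    def test_costlier_and_less_effective_is_dominated(self):
        inc = incremental(_result("a", 100.0, 0.5), _result("b", 50.0, 1.0))
        assert inc.label == "dominated"
        assert inc.quadrant == "NW"

    def test_northeast_decision_against_threshold(self):
        cheap_gain = incremental(_result("a", 1000.0, 1.1), _result("b", 0.0, 1.0),
                                 wtp=36000.0)
        assert cheap_gain.label == "cost_effective"
        assert cheap_gain.icer == pytest.approx(10000.0)
        dear_gain = incremental(_result("a", 50000.0, 1.1), _result("b", 0.0, 1.0),
                                wtp=36000.0)
        assert dear_gain.label == "not_cost_effective"

    def test_identical_arms_are_neither_dominant_nor_dominated(self):
        a = _result("a", 100.0, 1.0)
        inc = incremental(a, _result("b", 100.0, 1.0))
        assert inc.icer is None
        assert inc.quadrant is None
        assert inc.label not in ("dominant", "dominated")

    def test_mismatched_horizons_rejected(self):
        a = _result("a", 100.0, 1.0)
        b = _result("b", 100.0, 1.0)
        a.horizon_months, b.horizon_months = 120.0, 240.0
        with pytest.raises(ValidationError, match="horizons"):
            incremental(a, b)

    @given(
        st.floats(-1e5, 1e5).filter(lambda x: abs(x) > 1e-6),
        st.floats(-2.0, 2.0).filter(lambda x: abs(x) > 1e-9),
    )
    def test_quadrant_matches_sign_table_oracle(self, delta_cost, delta_effect):
        inc = incremental(_result("a", 1e6 + delta_cost, 3.0 + delta_effect),
                          _result("b", 1e6, 3.0))
        oracle = {(True, True): "NE", (True, False): "NW",
                  (False, True): "SE", (False, False): "SW"}[
                      (delta_cost > 0, delta_effect > 0)]
        assert inc.quadrant == oracle
        assert (inc.label == "dominant") == (delta_cost < 0 and delta_effect > 0)
        assert (inc.label == "dominated") == (delta_cost > 0 and delta_effect < 0)


class TestNetMonetaryBenefit:
    def test_zero_wtp_is_negative_cost(self):
        assert nmb(_result("a", 1234.0, 1.0), 0.0) == pytest.approx(-1234.0)

    def test_published_worked_value(self):
        assert nmb(_result("a", 55022.0, 1.724), 36000.0) == pytest.approx(7042.0)

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValidationError):
            nmb(_result("a", 1.0, 1.0), -1.0)

    @given(
        st.floats(1.0, 1e5),  # delta cost > 0
        st.floats(1e-4, 2.0),  # delta effect > 0 (NE quadrant)
        st.floats(0.0, 2e5),
    )
    def test_icer_decision_agrees_with_nmb_ranking(self, dc, de, wtp):
        a = _result("a", 1e5 + dc, 2.0 + de)
        b = _result("b", 1e5, 2.0)
        inc = incremental(a, b, wtp=wtp)
        assert (inc.icer <= wtp) == (nmb(a, wtp) >= nmb(b, wtp))


class TestOneWaySA:
    def test_equally_shared_cost_change_cancels_in_the_increment(self):
        # two arms on identical curves: a cost borne equally by both
        # cancels out of the increment entirely
        from pscea.config import from_mapping

        raw = {
            "reference_arm": "a",
            "utilities": {"pre_progression": 0.8, "post_progression": 0.5},
            "survival": {
                "pfs": {"family": "exponential", "params": {"rate": 0.1}},
                "os": {"family": "exponential", "params": {"rate": 0.05}},
            },
            "horizon_months": 240,
            "arms": [
                {"id": "a",
                 "pre_progression_cycle_costs": {"drug_acquisition": 100.0}},
                {"id": "b",
                 "pre_progression_cycle_costs": {"drug_acquisition": 160.0}},
            ],
        }
        config = from_mapping(raw)
        base = run_model(config)
        varied = copy.deepcopy(config)
        for arm_id in ("a", "b"):
            set_parameter(varied, f"arms.{arm_id}.end_of_life_cost", 2000.0)
        shifted = run_model(varied)
        b0 = base.incremental_for("b")
        b1 = shifted.incremental_for("b")
        assert b1.delta_cost == pytest.approx(b0.delta_cost, abs=1e-9)
        assert b1.delta_effect == pytest.approx(b0.delta_effect, abs=1e-12)

    def test_setting_a_parameter_to_its_base_value_reproduces_the_base_case(
            self, fixture_config):
        base = run_model(fixture_config)
        for path in ("utilities.pre_progression",
                     "arms.bev_pacl.hr_pfs",
                     "arms.eve_exe.pre_progression_cycle_costs.drug_acquisition"):
            varied = copy.deepcopy(fixture_config)
            set_parameter(varied, path, get_parameter(varied, path))
            rerun = run_model(varied)
            for arm_id, result in base.arm_results.items():
                assert rerun.arm_results[arm_id].total_cost == result.total_cost
                assert rerun.arm_results[arm_id].total_qalys == result.total_qalys

    def test_doubling_reference_drug_cost_flips_the_saving(self, fixture_config):
        base = run_model(fixture_config)
        assert base.incremental_for("bev_pacl").delta_cost < 0
        varied = copy.deepcopy(fixture_config)
        set_parameter(
            varied, "arms.eve_exe.pre_progression_cycle_costs.drug_acquisition",
            2 * 2447.75)
        flipped = run_model(varied)
        assert flipped.incremental_for("bev_pacl").delta_cost > \
            base.incremental_for("bev_pacl").delta_cost

    def test_owsa_table_layout_and_icer_columns(self, fixture_config):
        specs = [OwsaSpec("utilities.pre_progression", 0.36, 0.90),
                 OwsaSpec("arms.bev_pacl.hr_pfs", 0.725, 2.175)]
        table = one_way_sa(fixture_config, specs)
        assert set(table.columns) >= {
            "parameter", "comparator", "low_value", "high_value",
            "low_result", "high_result", "low_icer", "high_icer"}
        assert len(table) == len(specs) * len(fixture_config.comparator_ids)
        assert set(table["low_label"]).issubset(
            {"dominant", "dominated", "cost_effective", "not_cost_effective",
             "less_effective_and_cheaper"})

    def test_no_specs_rejected(self, fixture_config):
        fixture_config.owsa_specs = []
        with pytest.raises(ValidationError, match="no one-way"):
            one_way_sa(fixture_config)


class TestScenarios:
    def test_no_overrides_equals_base_case(self, fixture_config):
        base = run_model(fixture_config)
        rerun = scenario_run(fixture_config)
        for arm_id, result in base.arm_results.items():
            assert rerun.arm_results[arm_id].total_cost == result.total_cost
            assert rerun.arm_results[arm_id].total_qalys == result.total_qalys

    def test_zero_fixed_post_progression_survival_empties_the_state(
            self, fixture_config):
        run = scenario_run(fixture_config, fixed_pps=0.0)
        for result in run.arm_results.values():
            assert result.qalys_post == pytest.approx(0.0, abs=1e-12)

    def test_family_override_requires_ipd(self, fixture_config):
        with pytest.raises(ValidationError, match="frozen parameters"):
            scenario_run(fixture_config, family="loglogistic")

    def test_nested_family_override_barely_moves_results(self, fixture_config,
                                                         tmp_path):
        # constructed coincidence: on exponential data the Weibull fit
        # collapses onto the exponential fit, so swapping families should
        # leave the economics nearly unchanged
        for endpoint, rate in (("PFS", 1 / 9.0), ("OS", 1 / 36.0)):
            ipd = simulate_ipd(IpdSimSpec(
                n=4000, family="exponential", params=(rate,), seed=5,
                endpoint=endpoint))
            write_ipd(ipd, tmp_path / f"{endpoint}.csv")
            spec = fixture_config.survival[endpoint.lower()]
            spec.params = None
            spec.family = "weibull"
            spec.ipd_path = str(tmp_path / f"{endpoint}.csv")
        base = run_model(fixture_config)
        alt = scenario_run(fixture_config, family="exponential")
        for arm_id, result in base.arm_results.items():
            assert alt.arm_results[arm_id].total_cost == pytest.approx(
                result.total_cost, rel=0.01)
            assert alt.arm_results[arm_id].total_qalys == pytest.approx(
                result.total_qalys, rel=0.01)

    def test_dose_intensity_scenario_lowers_treatment_cost(self, fixture_config):
        base = run_model(fixture_config)
        rdi = scenario_run(fixture_config, apply_rdi=True)
        for arm_id in base.arm_results:
            assert rdi.arm_results[arm_id].cost_treatment_and_administration < \
                base.arm_results[arm_id].cost_treatment_and_administration
            assert rdi.arm_results[arm_id].total_qalys == pytest.approx(
                base.arm_results[arm_id].total_qalys)
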