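"""Unit tests for parameter estimation from follow-up records."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from htncea.estimation import (
    ControlRateEstimate,
    CostAdjustment,
    EstimationError,
    SalaryInputs,
    SF36_DIMENSIONS,
    StudyWindow,
    TransitionCountTable,
    adjust_cost,
    annual_transition_probabilities,
    annualize_study_probability,
    count_transitions,
    estimate_control_rate,
    estimate_control_rate_per_patient,
    estimate_state_utility,
    map_sf36_to_eq5d,
    probability_to_rate,
    rate_to_annual_probability,
    salary_cost,
    study_probability,
)


def make_records(rows):
    cols = ["patient_id", "arm", "visit_index", "sbp", "dbp", "state"]
    recs = pd.DataFrame(rows, columns=cols)
    for d in SF36_DIMENSIONS:
        recs[d] = 70.0
    return recs


class TestStudyProbability:
    def test_whole_cohort_denominator(self):
        # the tabulated convention: frequency over all analyzable patients
        t = TransitionCountTable({("L1", "prehypertension"): 383,
                                  ("prehypertension", "L1"): 101,
                                  ("L1", "L1"): 764}, total_n=1248)
        assert study_probability(t, "L1", "prehypertension") == pytest.approx(0.3069, abs=5e-5)
        assert study_probability(t, "prehypertension", "L1") == pytest.approx(0.0809, abs=5e-5)

    def test_absent_pair_is_zero(self):
        t = TransitionCountTable({("L1", "L1"): 3}, total_n=3)
        assert study_probability(t, "L3", "L1") == 0.0

    def test_origin_denominator_option(self):
        t = TransitionCountTable({("L1", "prehypertension"): 1, ("L1", "L1"): 3},
                                 total_n=4)
        assert study_probability(t, "L1", "prehypertension", denominator="origin") == 0.25

    def test_empty_table_rejected(self):
        t = TransitionCountTable({}, total_n=0)
        with pytest.raises(EstimationError):
            study_probability(t, "L1", "L2")

    def test_counts_must_sum_to_total(self):
        with pytest.raises(EstimationError):
            TransitionCountTable({("L1", "L1"): 2}, total_n=5)


class TestRateConversion:
    @pytest.mark.parametrize(
        "p, t, rate",
        [
            # oracle: -(1/t) ln(1-p) evaluated independently
            (0.3069, 2, 0.18329),
            (0.0809, 2, 0.04218),
            (0.0, 2, 0.0),
        ],
    )
    def test_probability_to_rate(self, p, t, rate):
        assert probability_to_rate(p, t) == pytest.approx(rate, abs=1e-5)

    @pytest.mark.parametrize(
        "rate, p",
        [(0.18329, 0.1675), (0.04218, 0.0413), (0.0, 0.0)],
    )
    def test_rate_to_annual_probability(self, rate, p):
        assert rate_to_annual_probability(rate) == pytest.approx(p, abs=5e-5)

    @pytest.mark.parametrize(
        "p2y, annual",
        [(0.0569, 0.0289), (0.0112, 0.0056), (0.0120, 0.0060)],
    )
    def test_two_year_annualization(self, p2y, annual):
        assert round(annualize_study_probability(p2y, 2.0), 4) == annual

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(EstimationError):
            probability_to_rate(1.0, 2.0)
        with pytest.raises(EstimationError):
            probability_to_rate(-0.1, 2.0)
        with pytest.raises(EstimationError):
            rate_to_annual_probability(-0.1)
        with pytest.raises(EstimationError):
            probability_to_rate(0.5, 0.0)

    @given(p=st.floats(0.0, 0.999))
    @settings(max_examples=200, deadline=None)
    def test_one_year_round_trip(self, p):
        assert rate_to_annual_probability(probability_to_rate(p, 1.0)) == pytest.approx(
            p, abs=1e-12
        )

    @given(
        p=st.floats(0.001, 0.99),
        q=st.floats(0.001, 0.99),
        t=st.floats(0.5, 10),
        t2=st.floats(0.5, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_p_and_t(self, p, q, t, t2):
        lo_p, hi_p = sorted([p, q])
        if lo_p < hi_p:
            assert annualize_study_probability(lo_p, t) < annualize_study_probability(hi_p, t)
        lo_t, hi_t = sorted([t, t2])
        if lo_t < hi_t:
            assert annualize_study_probability(p, hi_t) < annualize_study_probability(p, lo_t)


class TestCountTransitions:
    def test_baseline_vs_final_only(self):
        rows = []
        for pid in range(3):
            for v in (0, 5, 12):
                rows.append((f"p{pid}", "usual", v, 150, 95, "L1"))
        table = count_transitions(make_records(rows))
        assert table.counts == {("L1", "L1"): 3}
        assert table.total_n == 3

    def test_incomplete_patient_excluded(self):
        rows = [("a", "usual", 0, 150, 95, "L1"), ("a", "usual", 12, 125, 85, "prehypertension"),
                ("b", "usual", 0, 150, 95, "L1")]  # b never reaches the final visit
        table = count_transitions(make_records(rows))
        assert table.total_n == 1
        assert table.counts == {("L1", "prehypertension"): 1}


class TestAnnualTransitionTable:
    def test_normotension_dropped_by_default(self):
        # final-visit normotension is ignored, exactly as the source table does
        t = TransitionCountTable(
            {("L1", "normotension"): 17, ("L1", "prehypertension"): 383,
             ("L1", "L1"): 848}, total_n=1248)
        annual = annual_transition_probabilities(t, StudyWindow(2.0))
        assert round(annual[("L1", "prehypertension")], 4) == 0.1675

    def test_normotension_folding_option(self):
        t = TransitionCountTable(
            {("L1", "normotension"): 17, ("L1", "prehypertension"): 383,
             ("L1", "L1"): 848}, total_n=1248)
        annual = annual_transition_probabilities(t, StudyWindow(2.0), normotension="fold")
        # (383+17)/1248 = 0.3205 annualized
        assert round(annual[("L1", "prehypertension")], 4) == 0.1757


class TestControlRate:
    def base(self, sbp):
        rows = [("a", "usual", v, sbp, 70, "L1") for v in range(13)]
        return make_records(rows)

    def test_all_controlled(self):
        est = estimate_control_rate(self.base(118), "usual")
        assert est.control_rate == 1.0
        assert est.n_measurements == 12  # baseline excluded

    def test_120_is_not_controlled(self):
        assert estimate_control_rate(self.base(120), "usual").control_rate == 0.0

    def test_empty_arm_rejected(self):
        with pytest.raises(EstimationError):
            estimate_control_rate(self.base(118), "option2")

    def test_per_patient_variant_matches_for_balanced_data(self):
        recs = self.base(118)
        pooled = estimate_control_rate(recs, "usual").control_rate
        averaged = estimate_control_rate_per_patient(recs, "usual").control_rate
        assert pooled == averaged == 1.0

    def test_invalid_rate_rejected(self):
        with pytest.raises(EstimationError):
            ControlRateEstimate("x", 1.2, 5)


class TestSF36Mapping:
    def test_intercept(self):
        assert map_sf36_to_eq5d(dict.fromkeys(SF36_DIMENSIONS, 0.0)) == 0.03256

    def test_all_hundred(self):
        # oracle: intercept + 100 * (sum of the eight coefficients) = 1.04456;
        # the published linear model overpredicts at the healthy extreme
        assert map_sf36_to_eq5d([100.0] * 8) == pytest.approx(1.04456, abs=1e-10)

    def test_single_dimension(self):
        scores = dict.fromkeys(SF36_DIMENSIONS, 0.0)
        scores["pf"] = 100.0
        assert map_sf36_to_eq5d(scores) == pytest.approx(0.40256, abs=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(EstimationError):
            map_sf36_to_eq5d([101.0] + [50.0] * 7)

    @given(
        a=st.lists(st.floats(0, 50), min_size=8, max_size=8),
        b=st.lists(st.floats(0, 50), min_size=8, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine(self, a, b):
        f0 = map_sf36_to_eq5d([0.0] * 8)
        fa = map_sf36_to_eq5d(a)
        fb = map_sf36_to_eq5d(b)
        fab = map_sf36_to_eq5d([x + y for x, y in zip(a, b)])
        assert fa + fb - f0 == pytest.approx(fab, abs=1e-9)


class TestStateUtility:
    def test_constant_records_zero_width_ci(self):
        rows = [(f"p{i}", "usual", 0, 150, 95, "L1") for i in range(5)]
        recs = make_records(rows)
        mean, (lo, hi) = estimate_state_utility(recs, "L1")
        assert lo == pytest.approx(mean) and hi == pytest.approx(mean)

    def test_single_record_rejected(self):
        recs = make_records([("a", "usual", 0, 150, 95, "L1")])
        with pytest.raises(EstimationError):
            estimate_state_utility(recs, "L1")

    def test_recovers_target_mean(self):
        # scores drawn so the mapped utility is centred on the published
        # hypertension-L2 value 0.683
        from htncea.synthetic import sf36_means_for_utility

        rng = np.random.default_rng(42)
        level = sf36_means_for_utility(0.683)
        recs = make_records(
            [(f"p{i}", "usual", 0, 165, 102, "L2") for i in range(400)]
        )
        noise = rng.normal(0, 8, size=(400, 8))
        recs[list(SF36_DIMENSIONS)] = np.clip(level + noise, 0, 100)
        mean, (lo, hi) = estimate_state_utility(recs, "L2")
        assert mean == pytest.approx(0.683, abs=0.01)
        assert lo < 0.683 < hi


class TestCosts:
    def test_cny_conversion_at_base_year(self):
        adj = CostAdjustment(record_year=2021)
        assert adjust_cost(100.0, adj, currency="CNY") == pytest.approx(15.60)

    def test_eight_years_inflation(self):
        adj = CostAdjustment(record_year=2013)
        assert adjust_cost(100.0, adj) == pytest.approx(121.84, abs=0.005)

    def test_zero_inflation_identity(self):
        adj = CostAdjustment(record_year=2015, inflation_rate=0.0)
        assert adjust_cost(100.0, adj) == 100.0

    def test_backwards_adjustment_rejected(self):
        with pytest.raises(EstimationError):
            CostAdjustment(record_year=2022, base_year=2021)

    def test_salary_cost_one_hour(self):
        inputs = SalaryInputs(additional_hours=1.0)
        assert salary_cost(inputs) == pytest.approx(17979.40 / 2000)

    def test_salary_cost_full_year_identity(self):
        inputs = SalaryInputs(additional_hours=2000.0)
        assert salary_cost(inputs) == pytest.approx(17979.40)

    def test_salary_zero_hours(self):
        assert salary_cost(SalaryInputs(additional_hours=0.0)) == 0.0

    def test_invalid_salary_inputs(self):
        with pytest.raises(EstimationError):
            SalaryInputs(working_days=0.0)
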