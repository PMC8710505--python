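"""Unit and property tests for the Markov cohort engine."""

import numpy as np
import pytest

from htncea.model import (
    build_transition_matrix,
    discount_factor,
    mortality_lookup,
    run_cohort,
    total_outcomes,
)
from htncea.params import (
    ArmParameters,
    EconomicSettings,
    MortalityTable,
    ParameterError,
    ParameterSet,
)
from htncea.states import DEATH, STATE_INDEX, STATES

ZERO_MORT = MortalityTable({a: 0.0 for a in range(35, 105, 5)})


def minimal_params(**overrides):
    defaults = dict(
        transitions={},
        utilities={s: 1.0 for s in STATES if s != DEATH},
        costs={s: 0.0 for s in STATES if s != DEATH},
        mortality=ZERO_MORT,
        arm=ArmParameters(label="usual", control_rate=0.61,
                          human_cost=0.0, project_cost=0.0),
        economics=EconomicSettings(discount_rate=0.0),
    )
    defaults.update(overrides)
    return ParameterSet(**defaults)


class TestMortalityLookup:
    @pytest.mark.parametrize("age, q", [(67, 0.0172), (102, 0.4543), (35, 0.0012),
                                        (39.9, 0.0012), (100, 0.4543)])
    def test_band_lookup(self, age, q, arms):
        assert mortality_lookup(arms["usual"].mortality, age) == q

    def test_below_table_rejected(self, arms):
        with pytest.raises(ParameterError):
            mortality_lookup(arms["usual"].mortality, 30)


class TestDiscountFactor:
    def test_first_cycle_undiscounted(self):
        assert discount_factor(0.05, 0) == 1.0

    def test_one_cycle(self):
        assert discount_factor(0.05, 1) == pytest.approx(0.95238, abs=1e-5)

    def test_zero_rate(self):
        assert discount_factor(0.0, 40) == 1.0

    def test_negative_cycle_rejected(self):
        with pytest.raises(ParameterError):
            discount_factor(0.05, -1)


class TestBuildMatrix:
    def test_prehypertension_row_reference_arm(self, arms):
        # hand sum of the prehypertension off-diagonals plus the 35-39
        # mortality band: 0.0413+0.0056+0.0016+0.0014+0.0002+0.0011+0.0012
        ps = arms["usual"]
        m = build_transition_matrix(
            ps.transitions, ps.mortality, 35, ps.arm,
            ps.economics.reference_control_rate,
        )
        i = STATE_INDEX["prehypertension"]
        assert m[i, STATE_INDEX["L1"]] == pytest.approx(0.0413)
        assert m[i, STATE_INDEX[DEATH]] == pytest.approx(0.0012)
        assert m[i, i] == pytest.approx(0.9476)
        assert m.sum(axis=1) == pytest.approx(np.ones(9))

    def test_death_row_absorbing(self, arms):
        ps = arms["usual"]
        m = build_transition_matrix(
            ps.transitions, ps.mortality, 80, ps.arm,
            ps.economics.reference_control_rate,
        )
        i = STATE_INDEX[DEATH]
        expected = np.zeros(9)
        expected[i] = 1.0
        assert m[i] == pytest.approx(expected)

    def test_no_transitions_no_mortality_gives_identity(self):
        ps = minimal_params()
        m = build_transition_matrix(ps.transitions, ps.mortality, 40, ps.arm, 0.61)
        assert m == pytest.approx(np.eye(9))

    def test_improvement_scaling(self, arms):
        ps = arms["option2"]
        m = build_transition_matrix(
            ps.transitions, ps.mortality, 35, ps.arm,
            ps.economics.reference_control_rate,
        )
        i, j = STATE_INDEX["L1"], STATE_INDEX["prehypertension"]
        assert m[i, j] == pytest.approx(0.1675 * 0.69 / 0.61)
        # worsening transitions are untouched
        assert m[i, STATE_INDEX["L2"]] == pytest.approx(0.0072)

    def test_overflowing_row_rejected(self):
        ps = minimal_params(transitions={("L3", "prehypertension"): 0.9})
        ps.arm.control_rate = 1.0
        with pytest.raises(ParameterError):
            build_transition_matrix(ps.transitions, ps.mortality, 40, ps.arm, 0.5)


class TestRunCohort:
    def test_identity_dynamics_accumulate_full_qalys(self):
        trace = run_cohort(minimal_params())
        assert trace.totals.qaly == pytest.approx(65.0)
        assert trace.totals.ly == pytest.approx(65.0)
        assert trace.fraction_dead == 0.0

    def test_immediate_death_gives_one_life_year(self):
        mort = MortalityTable({a: 1.0 for a in range(35, 105, 5)})
        trace = run_cohort(minimal_params(mortality=mort))
        assert trace.totals.ly == pytest.approx(1.0)
        assert trace.trace[DEATH].iloc[1:].to_numpy() == pytest.approx(
            np.ones(65)
        )

    def test_lifetime_absorption_matches_reported_level(self, arms):
        # roughly 99% of a cohort entering at 35 is dead after 65 cycles
        trace = run_cohort(arms["usual"])
        assert trace.fraction_dead == pytest.approx(0.992, rel=0.01)

    def test_conservation_every_cycle(self, arms):
        for ps in arms.values():
            occ = run_cohort(ps).trace[list(STATES)].to_numpy()
            assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-12

    def test_death_occupancy_non_decreasing(self, arms):
        dead = run_cohort(arms["option2"]).trace[DEATH].to_numpy()
        assert (np.diff(dead) >= -1e-15).all()

    def test_discount_monotonicity(self, fresh_arms):
        from dataclasses import replace

        ps = fresh_arms["usual"]
        totals = []
        for r in (0.0, 0.03, 0.05, 0.08):
            ps.economics = replace(ps.economics, discount_rate=r)
            totals.append(run_cohort(ps).totals)
        costs = [t.cost for t in totals]
        qalys = [t.qaly for t in totals]
        assert costs == sorted(costs, reverse=True)
        assert qalys == sorted(qalys, reverse=True)

    def test_qaly_ordering_tracks_control_rates(self, arms):
        q = {name: run_cohort(ps).totals.qaly for name, ps in arms.items()}
        assert q["option2"] >= q["option1"] >= q["usual"]

    def test_two_state_geometric_series_closed_form(self):
        # alive/dead reduction with constant hazard and no discounting:
        # total LYs must equal sum_{k=0}^{64} (1-q)^k
        q = 0.07
        mort = MortalityTable({a: q for a in range(35, 105, 5)})
        trace = run_cohort(minimal_params(mortality=mort))
        expected = sum((1 - q) ** k for k in range(65))
        assert trace.totals.ly == pytest.approx(expected, rel=1e-12)

    def test_single_cycle_reward_arithmetic(self):
        # everyone in L1 for one cycle: cost = chy1 + per-capita intervention,
        # QALY = U_1
        econ = EconomicSettings(discount_rate=0.0, horizon=1,
                                initial_distribution={"L1": 1.0})
        arm = ArmParameters(label="usual", control_rate=0.61,
                            human_cost=346.10, project_cost=14.72)
        ps = minimal_params(economics=econ, arm=arm)
        ps.costs["L1"] = 150.87
        ps.utilities["L1"] = 0.65525
        t = run_cohort(ps).totals
        assert t.qaly == pytest.approx(0.65525)
        assert t.ly == pytest.approx(1.0)
        assert t.cost == pytest.approx(150.87 + (346.10 + 14.72) / (415 * 1.5))

    def test_undiscounted_linearity_over_cycles(self):
        econ1 = EconomicSettings(discount_rate=0.0, horizon=1,
                                 initial_distribution={"L2": 1.0})
        econ2 = EconomicSettings(discount_rate=0.0, horizon=2,
                                 initial_distribution={"L2": 1.0})
        ps1 = minimal_params(economics=econ1)
        ps2 = minimal_params(economics=econ2)
        for ps in (ps1, ps2):
            ps.costs["L2"] = 187.08
        t1, t2 = run_cohort(ps1).totals, run_cohort(ps2).totals
        assert t2.cost == pytest.approx(2 * t1.cost)
        assert t2.qaly == pytest.approx(2 * t1.qaly)

    def test_total_outcomes_matches_trace_totals(self, arms):
        trace = run_cohort(arms["usual"])
        assert total_outcomes(trace) == trace.totals

    def test_half_cycle_correction_reduces_life_years(self, arms):
        plain = run_cohort(arms["usual"]).totals
        corrected = run_cohort(arms["usual"], half_cycle=True).totals
        assert corrected.ly < plain.ly
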