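import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drscreen import (
    ModelParams,
    cataract_qaly_gain,
    discounted_qalys,
    life_expectancy,
    run_cohort,
    stdr_qaly_gain,
    transition_row,
)

from conftest import constant_table


class TestTransitionRow:
    def test_zero_mortality_treated_row(self):
        lt = constant_table(0.0)
        row = transition_row(ModelParams(), lt, 59, "stdr", treated=True)
        assert row.p_stdr == pytest.approx(0.98)
        assert row.p_blind == pytest.approx(0.02)
        assert row.p_dead == 0.0

    def test_death_first_then_progression(self):
        # qx=0.02, untreated: dead 1.9*0.02, progression among survivors
        lt = constant_table(0.02)
        row = transition_row(ModelParams(), lt, 59, "stdr", treated=False)
        assert row.p_dead == pytest.approx(0.038, abs=1e-15)
        assert row.p_blind == pytest.approx(0.09 * 0.962, abs=1e-15)
        assert row.p_stdr == pytest.approx(0.87542, abs=1e-12)
        assert row.p_stdr + row.p_blind + row.p_dead == pytest.approx(1.0, abs=1e-12)

    def test_blind_state_stay_or_die(self):
        lt = constant_table(0.02)
        row = transition_row(ModelParams(), lt, 59, "blind")
        assert row.p_dead == pytest.approx(2.34 * 0.02, abs=1e-15)
        assert row.p_blind == pytest.approx(0.9532, abs=1e-12)
        assert row.p_stdr == 0.0

    def test_combined_blind_uplift_switch(self):
        lt = constant_table(0.01)
        row = transition_row(
            ModelParams(blind_uplift_combined=True), lt, 59, "blind"
        )
        assert row.p_dead == pytest.approx(1.9 * 2.34 * 0.01)

    def test_dead_state_has_no_row(self):
        lt = constant_table(0.02)
        with pytest.raises(ValueError, match="absorbing"):
            transition_row(ModelParams(), lt, 59, "dead")

    @given(
        q=st.floats(0.0, 1.0),
        rr=st.floats(0.0, 4.0),
        p_prog=st.floats(0.0, 1.0),
    )
    def test_rows_always_sum_to_one(self, q, rr, p_prog):
        lt = constant_table(q)
        params = ModelParams(rr_diabetes=rr, rr_blind=rr, p_blind_untreated=p_prog)
        for state in ("stdr", "blind"):
            row = transition_row(params, lt, 60, state)
            assert abs(row.p_stdr + row.p_blind + row.p_dead - 1.0) <= 1e-12


class TestCohortTrace:
    def test_certain_death_in_one_cycle(self):
        lt = constant_table(1.0)
        trace = run_cohort(ModelParams(start_age=59, horizon=3), lt)
        assert trace.occ_dead[1] == 1.0
        assert trace.alive[1] == 0.0

    def test_no_flow_case_stays_in_stdr(self):
        lt = constant_table(0.0)
        params = ModelParams(p_blind_untreated=0.0, horizon=30)
        trace = run_cohort(params, lt)
        np.testing.assert_allclose(trace.occ_stdr, 1.0)

    def test_geometric_survival_closed_form(self):
        lt = constant_table(0.1)
        params = ModelParams(
            p_blind_untreated=0.0, rr_diabetes=1.0, rr_blind=1.0, horizon=40
        )
        trace = run_cohort(params, lt)
        t = np.arange(41)
        np.testing.assert_allclose(trace.alive, 0.9**t, atol=1e-12)

    def test_occupancy_conserved_and_dead_monotone(self, fixture_lt):
        trace = run_cohort(ModelParams(), fixture_lt)
        assert trace.horizon >= 40
        total = trace.occ_stdr + trace.occ_blind + trace.occ_dead
        np.testing.assert_allclose(total, 1.0, atol=1e-10)
        assert np.all(np.diff(trace.occ_dead) >= -1e-12)
        assert trace.alive[-1] == pytest.approx(0.0, abs=1e-12)

    def test_horizon_past_table_rejected(self):
        lt = constant_table(0.1, 50, 80)
        with pytest.raises(ValueError, match="terminal"):
            run_cohort(ModelParams(start_age=59, horizon=40), lt)


class TestLifeExpectancy:
    def test_certain_death_gives_zero(self):
        lt = constant_table(1.0)
        assert life_expectancy(run_cohort(ModelParams(horizon=5), lt)) == 0.0

    def test_geometric_series_limit(self):
        # sum of 0.9^t for t>=1 converges to 9
        lt = constant_table(0.1, 50, 450)
        params = ModelParams(p_blind_untreated=0.0, rr_diabetes=1.0, rr_blind=1.0,
                             start_age=59, horizon=380)
        le = life_expectancy(run_cohort(params, lt))
        assert le == pytest.approx(9.0, abs=1e-9)

    def test_treatment_extends_life(self, fixture_lt):
        # blindness carries the higher mortality uplift, so slowing
        # progression must extend life expectancy
        params = ModelParams()
        le_t = life_expectancy(run_cohort(params, fixture_lt, treated=True))
        le_u = life_expectancy(run_cohort(params, fixture_lt, treated=False))
        assert le_t > le_u

    def test_half_cycle_correction_adds_about_half_year(self, fixture_lt):
        trace = run_cohort(ModelParams(), fixture_lt)
        assert life_expectancy(trace, half_cycle_correction=True) == pytest.approx(
            life_expectancy(trace) + 0.5, abs=1e-9
        )


class TestDiscountedQalys:
    def test_single_cycle_discounted_once(self):
        lt = constant_table(0.0, 50, 70)
        params = ModelParams(u_stdr=1.0, u_blind=1.0, p_blind_untreated=0.0,
                             horizon=1, discount_rate=0.03)
        q = discounted_qalys(run_cohort(params, lt), params)
        assert q == pytest.approx(1 / 1.03, abs=1e-12)

    def test_zero_discount_full_utility_equals_le(self, fixture_lt):
        params = ModelParams(u_stdr=1.0, u_blind=1.0, discount_rate=0.0)
        trace = run_cohort(params, fixture_lt)
        assert discounted_qalys(trace, params) == pytest.approx(
            life_expectancy(trace), abs=1e-10
        )

    @given(rate=st.floats(0.0, 0.2))
    def test_monotone_non_increasing_in_discount_rate(self, fixture_lt, rate):
        params = ModelParams(discount_rate=rate)
        trace = run_cohort(params, fixture_lt)
        assert discounted_qalys(trace, params) <= discounted_qalys(
            trace, params.with_(discount_rate=0.0)
        ) + 1e-12

    def test_fundamental_matrix_closed_form(self):
        # constant-mortality table: discounted QALYs have the matrix
        # closed form pi0 . dQ (I - (dQ)^H)(I - dQ)^-1 u
        q, horizon = 0.02, 120
        lt = constant_table(q, 50, 200)
        params = ModelParams(start_age=59, horizon=horizon)
        p_dead_s = params.rr_diabetes * q
        p_dead_b = params.rr_blind * q
        p_blind = params.p_blind_untreated * (1 - p_dead_s)
        Q = np.array([[1 - p_dead_s - p_blind, p_blind], [0.0, 1 - p_dead_b]])
        u = np.array([params.u_stdr, params.u_blind])
        d = 1 / (1 + params.discount_rate)
        dQ = d * Q
        eye = np.eye(2)
        series = dQ @ (eye - np.linalg.matrix_power(dQ, horizon)) @ np.linalg.inv(eye - dQ)
        expected = np.array([1.0, 0.0]) @ series @ u
        got = discounted_qalys(run_cohort(params, lt), params)
        assert got == pytest.approx(expected, abs=1e-9)


class TestQalyGains:
    def test_equal_rates_give_zero_gain(self, fixture_lt):
        params = ModelParams(p_blind_treated=0.09, p_blind_untreated=0.09)
        assert stdr_qaly_gain(params, fixture_lt) == pytest.approx(0.0, abs=1e-12)

    def test_gain_positive_at_default_parameters(self, fixture_lt):
        assert stdr_qaly_gain(ModelParams(), fixture_lt) > 0

    @pytest.mark.parametrize("rates", [(0.02, 0.04, 0.06, 0.09)])
    def test_gain_monotone_decreasing_in_treated_rate(self, fixture_lt, rates):
        gains = [
            stdr_qaly_gain(ModelParams(p_blind_treated=r), fixture_lt) for r in rates
        ]
        assert all(a > b for a, b in zip(gains, gains[1:]))

    def test_cataract_zero_gain_when_no_utility_gain(self, fixture_lt):
        assert cataract_qaly_gain(ModelParams(u_gain_cataract=0.0), fixture_lt) == 0.0

    def test_cataract_undamped_sum(self):
        lt = constant_table(0.0, 50, 80)
        params = ModelParams(
            rr_diabetes=1.0, discount_rate=0.0, hrqol_decline=0.0,
            start_age=59, horizon=10,
        )
        assert cataract_qaly_gain(params, lt) == pytest.approx(2.0, abs=1e-12)
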