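import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drscreen import (
    DsaSpec,
    PsaSpec,
    ceac,
    evaluate_scenario,
    fit_beta_moments,
    fit_gamma_moments,
    one_way_dsa,
    probability_cost_effective,
    run_psa,
)
from drscreen.sensitivity import sample_parameters


class TestMomentFits:
    def test_gamma_laser_cost_example(self):
        shape, scale = fit_gamma_moments(12_000, 3_000)
        assert shape == pytest.approx(16.0)
        assert scale == pytest.approx(750.0)

    @given(mean=st.floats(1e-3, 1e6))
    def test_quarter_sd_rule_always_shape_16(self, mean):
        shape, _ = fit_gamma_moments(mean, 0.25 * mean)
        assert shape == pytest.approx(16.0, rel=1e-12)

    @given(mean=st.floats(0.01, 0.99), sd_frac=st.floats(0.05, 0.4))
    def test_gamma_round_trip_exact(self, mean, sd_frac):
        sd = sd_frac * mean
        shape, scale = fit_gamma_moments(mean, sd)
        assert shape * scale == pytest.approx(mean, rel=1e-12)
        assert np.sqrt(shape) * scale == pytest.approx(sd, rel=1e-12)

    def test_gamma_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_gamma_moments(0.0, 1.0)

    def test_beta_utility_example(self):
        alpha, beta = fit_beta_moments(0.70, 0.175)
        assert alpha == pytest.approx(4.1, abs=1e-9)
        assert beta == pytest.approx(1.757142857, abs=1e-9)

    def test_beta_transition_rate_within_variance_bound(self):
        alpha, beta = fit_beta_moments(0.09, 0.0225)
        mean = alpha / (alpha + beta)
        var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
        assert mean == pytest.approx(0.09, rel=1e-12)
        assert np.sqrt(var) == pytest.approx(0.0225, rel=1e-12)

    def test_beta_variance_bound_violation_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            fit_beta_moments(0.5, 0.5)

    def test_fitted_distributions_against_scipy(self):
        from scipy import stats

        shape, scale = fit_gamma_moments(12_000, 3_000)
        m, v = stats.gamma.stats(a=shape, scale=scale, moments="mv")
        assert m == pytest.approx(12_000) and np.sqrt(v) == pytest.approx(3_000)
        alpha, beta = fit_beta_moments(0.09, 0.0225)
        m, v = stats.beta.stats(alpha, beta, moments="mv")
        assert m == pytest.approx(0.09) and np.sqrt(v) == pytest.approx(0.0225)

    def test_empirical_moments_within_3_se(self):
        # Monte-Carlo oracle: 10^6 seeded draws reproduce the fitted moments
        rng = np.random.default_rng(2024)
        n = 1_000_000
        shape, scale = fit_gamma_moments(12_000, 3_000)
        draws = rng.gamma(shape, scale, size=n)
        assert abs(draws.mean() - 12_000) < 3 * 3_000 / np.sqrt(n)
        assert draws.std() == pytest.approx(3_000, rel=0.01)
        alpha, beta = fit_beta_moments(0.70, 0.175)
        bdraws = rng.beta(alpha, beta, size=n)
        assert abs(bdraws.mean() - 0.70) < 3 * 0.175 / np.sqrt(n)
        assert bdraws.std() == pytest.approx(0.175, rel=0.01)


class TestOneWayDsa:
    def test_zero_range_gives_zero_spans(self, kerala, fixture_lt):
        spec = DsaSpec(low_factor=1.0, high_factor=1.0)
        table = one_way_dsa(kerala, fixture_lt, spec)
        assert np.allclose(table["span"], 0.0)
        assert np.allclose(table["icer_low"], table["icer_central"])

    def test_utilities_dominate_span_ordering(self, kerala, fixture_lt):
        table = one_way_dsa(kerala, fixture_lt)
        top2 = set(table["parameter"].iloc[:2])
        assert top2 == {"u_stdr", "u_blind"}
        cost_spans = table.set_index("parameter")["span"]
        assert cost_spans["u_stdr"] > cost_spans["laser_package"]
        assert cost_spans["u_stdr"] > cost_spans["cataract_surgery"]

    def test_laser_leg_matches_linear_propagation(self, kerala, fixture_lt):
        # laser cost does not touch QALYs, so the span is exactly
        # 20% of the laser package spend divided by total QALYs
        table = one_way_dsa(kerala, fixture_lt).set_index("parameter")
        res = evaluate_scenario(kerala, fixture_lt)
        expected = 0.2 * 345 * 12_000 / res.total_qalys
        assert table.loc["laser_package", "span"] == pytest.approx(expected, rel=1e-9)

    def test_single_parameter_table(self, kerala, fixture_lt):
        table = one_way_dsa(kerala, fixture_lt, DsaSpec(parameters=("u_stdr",)))
        assert len(table) == 1

    def test_probability_legs_clipped_with_warning(self, kerala, fixture_lt, caplog):
        high = kerala.with_(params=kerala.params.with_(u_stdr=0.95))
        with caplog.at_level("WARNING", logger="drscreen.sensitivity"):
            one_way_dsa(high, fixture_lt, DsaSpec(parameters=("u_stdr",)))
        assert "clipped" in caplog.text


class TestPsa:
    def test_same_seed_identical_draws(self, kerala, fixture_lt):
        spec = PsaSpec(n_iterations=50)
        a = run_psa(kerala, fixture_lt, spec, seed=7)
        b = run_psa(kerala, fixture_lt, spec, seed=7)
        assert a.frame.equals(b.frame)

    def test_different_seeds_differ(self, kerala, fixture_lt):
        spec = PsaSpec(n_iterations=20)
        a = run_psa(kerala, fixture_lt, spec, seed=1)
        b = run_psa(kerala, fixture_lt, spec, seed=2)
        assert not a.frame.equals(b.frame)

    def test_parameter_streams_stable_under_set_changes(self, kerala):
        full = sample_parameters(kerala, PsaSpec(n_iterations=100), seed=3)
        fewer = sample_parameters(
            kerala,
            PsaSpec(n_iterations=100, families={"u_stdr": "beta", "laser_package": "gamma"}),
            seed=3,
        )
        np.testing.assert_array_equal(full["u_stdr"], fewer["u_stdr"])
        np.testing.assert_array_equal(full["laser_package"], fewer["laser_package"])

    def test_sampled_values_respect_domains(self, kerala, fixture_lt):
        draws = sample_parameters(kerala, PsaSpec(n_iterations=2_000), seed=11)
        for col in ("u_stdr", "u_blind", "p_blind_treated", "p_blind_untreated"):
            assert draws[col].between(0, 1).all()
        for col in ("laser_package", "cataract_surgery", "rr_blind"):
            assert (draws[col] > 0).all()

    def test_vanishing_sd_collapses_to_central_icer(self, kerala, fixture_lt):
        central = evaluate_scenario(kerala, fixture_lt).icer
        spec = PsaSpec(n_iterations=25, sd_fraction=1e-9)
        draws = run_psa(kerala, fixture_lt, spec, seed=5)
        np.testing.assert_allclose(draws.frame["icer"], central, rtol=1e-5)

    def test_ordering_enforcement_flag(self, kerala, fixture_lt):
        spec = PsaSpec(n_iterations=300, enforce_treated_below_untreated=True)
        draws = run_psa(kerala, fixture_lt, spec, seed=13)
        assert (
            draws.frame["p_blind_treated"] <= draws.frame["p_blind_untreated"]
        ).all()


class TestCeac:
    def test_monotone_and_bounded(self, kerala, fixture_lt):
        draws = run_psa(kerala, fixture_lt, PsaSpec(n_iterations=400), seed=9)
        curve = ceac(draws)
        assert curve["probability"].between(0, 1).all()
        assert (curve["probability"].diff().dropna() >= 0).all()

    def test_zero_wtp_probability_zero(self, kerala, fixture_lt):
        draws = run_psa(kerala, fixture_lt, PsaSpec(n_iterations=100), seed=4)
        assert ceac(draws, [0.0])["probability"].iloc[0] == 0.0

    def test_saturates_at_one_when_qalys_positive(self, kerala, fixture_lt):
        # narrow distributions keep every drawn QALY total positive, so
        # the curve must reach 1 in the large-wtp limit
        spec = PsaSpec(n_iterations=200, sd_fraction=0.05)
        draws = run_psa(kerala, fixture_lt, spec, seed=6)
        assert (draws.frame["total_qalys"] > 0).all()
        assert ceac(draws, [1e12])["probability"].iloc[0] == 1.0

    def test_probability_at_gdp_threshold_in_unit_interval(self, kerala, fixture_lt):
        draws = run_psa(kerala, fixture_lt, PsaSpec(n_iterations=400), seed=8)
        p = probability_cost_effective(draws, 144_000.0)
        assert 0.0 <= p <= 1.0

    def test_wtp_grid_must_include_gdp_threshold(self):
        with pytest.raises(ValueError, match="144"):
            PsaSpec(wtp_grid=(0.0, 100_000.0))
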