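"""Cohort-model mechanics: mortality mixing, quit transitions, traces, scaling."""

import numpy as np
import pytest

import dcea
from dcea.markov import (
    ModelSettings,
    annual_quit_probability,
    per_smoker_lifetime_outcomes,
    population_arm_outcomes,
    run_cohort_trace,
    smoker_mortality_rate,
)
from dcea.parameters import PopulationSpec

from conftest import make_externals, make_sample


class TestSmokerMortality:
    def test_no_differential_risk_recovers_all_cause(self):
        assert smoker_mortality_rate(0.01, 0.2, 0.3, 0.5, 1.0, 1.0) == pytest.approx(0.01)

    def test_mixture_inversion(self):
        m_s = smoker_mortality_rate(0.01, 0.2, 0.3, 0.5, 1.11, 2.0)
        assert m_s == pytest.approx(0.01 / 0.72027, rel=1e-4)
        # population-weighted average of the status-specific rates is all-cause
        recon = 0.2 * m_s + 0.3 * m_s / 1.11 + 0.5 * m_s / 2.0
        assert recon == pytest.approx(0.01, abs=1e-15)

    def test_single_group_population(self):
        assert smoker_mortality_rate(0.03, 1.0, 0.0, 0.0, 1.11, 2.0) == pytest.approx(0.03)

    def test_smokers_die_more_than_average_when_rrs_exceed_one(self):
        m_s = smoker_mortality_rate(0.01, 0.2, 0.3, 0.5, 1.11, 2.0)
        assert m_s > 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            smoker_mortality_rate(1.2, 0.2, 0.3, 0.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            smoker_mortality_rate(0.01, 0.2, 0.3, 0.5, -1.0, 1.0)


class TestQuitProbability:
    def test_first_cycle_active_uses_intervention_rate(self):
        assert annual_quit_probability(0.19, 1.0, True, "varenicline") == pytest.approx(0.19)

    def test_later_cycles_use_background(self):
        p = annual_quit_probability(0.19, 1.36, is_first_cycle=False, arm="varenicline",
                                    background_quit=0.02)
        assert p == pytest.approx(0.02 * 1.36)

    def test_zero_relative_risk(self):
        assert annual_quit_probability(0.13, 0.0, True, "ecigarette") == 0.0

    def test_no_intervention_first_cycle_uses_background(self):
        p = annual_quit_probability(0.5, 1.0, is_first_cycle=True, arm="none",
                                    background_quit=0.02)
        assert p == pytest.approx(0.02)

    def test_clamped_to_unit_interval(self):
        assert annual_quit_probability(0.9, 2.0, True, "varenicline") == 1.0


class TestCohortTrace:
    def test_immortal_undiscounted_cohort_conserves_person_years(self):
        sample = make_sample()
        ext = make_externals(mortality=0.0, incidence=0.0)
        settings = ModelSettings(discount_rate=0.0, background_quit_rate=0.0)
        # zero quit as well: quit rates scaled by rr=1 but background 0
        tr = run_cohort_trace(sample, ext, 1, "none", settings, entry_age=30)
        assert tr.total_qalys == pytest.approx(100 - 30)  # one QALY per cycle to the cap
        tr.check_invariants()

    def test_two_cycle_discount_closed_form(self):
        sample = make_sample()
        ext = make_externals()
        settings = ModelSettings(discount_rate=0.035, background_quit_rate=0.0, age_cap=100)
        tr = run_cohort_trace(sample, ext, 1, "none", settings, entry_age=75)
        # ages 75..99 alive; per-cycle utility 1 discounted at (1.035)^-t
        expected = sum(1.035 ** (-t) for t in range(100 - 75))
        assert tr.total_qalys == pytest.approx(expected, rel=1e-12)

    def test_certain_quit_first_cycle_empties_smoker_state(self):
        sample = make_sample(quit_rate_varenicline=1.0)
        ext = make_externals(mortality=0.01)
        settings = ModelSettings()
        tr = run_cohort_trace(sample, ext, 1, "varenicline", settings, entry_age=40)
        assert tr.smoker[1] == 0.0
        assert tr.former[1] == pytest.approx(1.0 * (1 - 0.01))  # survivors of cycle-1 death
        tr.check_invariants()

    def test_trace_invariants_on_realistic_inputs(self, mean_sample, externals):
        settings = ModelSettings()
        for q, arm in [(1, "none"), (3, "varenicline"), (5, "ecigarette")]:
            tr = run_cohort_trace(mean_sample, externals, q, arm, settings, entry_age=30)
            tr.check_invariants()
            assert 0 <= tr.total_qalys <= 100 - 30
            assert tr.total_costs >= 0

    def test_tidy_export_shape(self, mean_sample, externals):
        tr = run_cohort_trace(mean_sample, externals, 2, "none", ModelSettings(), 60)
        df = tr.to_frame()
        assert set(df.columns) >= {"cycle", "age", "smoker", "former", "dead",
                                   "disease", "events", "disc_qaly", "disc_cost"}
        assert len(df) == (100 - 60) * 6  # cycles x diseases


class TestPerSmokerAggregation:
    def test_degenerate_age_distribution_equals_single_trace(self, mean_sample, externals):
        settings = ModelSettings(entry_age_min=40, entry_age_max=40)
        q, c = per_smoker_lifetime_outcomes(mean_sample, externals, 2, "none", settings)
        tr = run_cohort_trace(mean_sample, externals, 2, "none", settings, 40)
        assert q == pytest.approx(tr.total_qalys, rel=1e-12)
        assert c == pytest.approx(tr.total_costs, rel=1e-12)

    def test_two_age_mixture_is_arithmetic_mean(self, mean_sample, externals):
        settings = ModelSettings(entry_age_min=40, entry_age_max=41)
        q, c = per_smoker_lifetime_outcomes(mean_sample, externals, 2, "none", settings)
        parts = [
            run_cohort_trace(mean_sample, externals, 2, "none", settings, a)
            for a in (40, 41)
        ]
        assert q == pytest.approx(np.mean([t.total_qalys for t in parts]), rel=1e-12)
        assert c == pytest.approx(np.mean([t.total_costs for t in parts]), rel=1e-12)

    def test_uniform_weights_match_brute_force_loop(self, mean_sample, externals):
        settings = ModelSettings()
        q, c = per_smoker_lifetime_outcomes(mean_sample, externals, 1, "varenicline", settings)
        traces = [
            run_cohort_trace(mean_sample, externals, 1, "varenicline", settings, a)
            for a in settings.entry_ages
        ]
        assert q == pytest.approx(np.mean([t.total_qalys for t in traces]), rel=1e-12)
        assert c == pytest.approx(np.mean([t.total_costs for t in traces]), rel=1e-12)


class TestPopulationScaling:
    def test_zero_uptake_gives_zero_increment(self, externals):
        sample = make_sample(**{f"uptake_imd{q}": 0.0 for q in range(1, 6)})
        pop = PopulationSpec("toy", 1e6, (0.2,) * 5)
        settings = ModelSettings()
        active = population_arm_outcomes(sample, externals, pop, "varenicline", settings)
        none = population_arm_outcomes(sample, externals, pop, "none", settings)
        np.testing.assert_allclose(active.qalys, none.qalys, rtol=1e-12)
        np.testing.assert_allclose(active.costs, none.costs, rtol=1e-12)

    def test_linear_in_population_size(self, mean_sample, externals):
        settings = ModelSettings()
        p1 = PopulationSpec("a", 1e6, (0.2,) * 5)
        p2 = PopulationSpec("b", 2e6, (0.2,) * 5)
        o1 = population_arm_outcomes(mean_sample, externals, p1, "varenicline", settings)
        o2 = population_arm_outcomes(mean_sample, externals, p2, "varenicline", settings)
        np.testing.assert_allclose(2 * o1.qalys, o2.qalys, rtol=1e-12)

    def test_single_quintile_matches_direct_computation(self, mean_sample, externals):
        settings = ModelSettings()
        pop = PopulationSpec("one", 1e5, (1.0, 0.0, 0.0, 0.0, 0.0))
        # degenerate shares break the sum-to-one? they sum to 1; fine
        out = population_arm_outcomes(mean_sample, externals, pop, "varenicline", settings)
        n_smokers = 1e5 * mean_sample.prevalence(1)
        u = mean_sample.uptake(1)
        q_v, c_v = per_smoker_lifetime_outcomes(mean_sample, externals, 1, "varenicline", settings)
        q_0, c_0 = per_smoker_lifetime_outcomes(mean_sample, externals, 1, "none", settings)
        expected_q = n_smokers * (q_0 + u * (q_v - q_0))
        assert out.qalys[0] == pytest.approx(expected_q, abs=1e-9 * abs(expected_q))
        assert out.qalys[1:].sum() == 0.0

    def test_equal_quintile_inputs_give_identical_outcomes(self, flat_externals):
        book = dcea.flatten_book(dcea.fixture_parameter_book("england"))
        sample = dcea.sample_at_means(book)
        settings = ModelSettings()
        results = [
            per_smoker_lifetime_outcomes(sample, flat_externals, q, "varenicline", settings)
            for q in range(1, 6)
        ]
        for q, c in results[1:]:
            assert q == pytest.approx(results[0][0], abs=1e-9)
            assert c == pytest.approx(results[0][1], abs=1e-9)


class TestMonotonicity:
    def test_higher_quit_rate_never_hurts(self, externals):
        # smokers worse off than former smokers in utility and risk
        common = {f"cost_{d}": 1000.0 for d in
                  ("lung_cancer", "chd", "copd", "mi", "stroke", "asthma_exacerbation")}
        common.update(hrqol_smoker=-0.034, rr_death_svf=1.11)
        base = make_sample(quit_rate_varenicline=0.19, **common)
        better = make_sample(quit_rate_varenicline=0.40, **common)
        ext = dcea.generate_external_inputs(0, "default")
        settings = ModelSettings()
        q_base, c_base = per_smoker_lifetime_outcomes(base, ext, 1, "varenicline", settings)
        q_more, c_more = per_smoker_lifetime_outcomes(better, ext, 1, "varenicline", settings)
        assert q_more >= q_base
        assert c_more <= c_base  # disease costs fall; intervention cost identical (0)
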