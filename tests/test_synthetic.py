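"""Synthetic external tables, packaged fixtures and toy problems."""

import numpy as np
import pytest

import dcea
from dcea.external import available_scenarios, generate_external_inputs
from dcea.fixtures import (
    build_hrqol_covariance,
    fixture_parameter_book,
    flatten_book,
    load_book,
    save_book,
)


class TestExternalInputs:
    def test_scenarios_available(self):
        assert {"default", "flat", "steep-gradient"} <= set(available_scenarios())

    def test_deterministic_under_seed(self):
        a = generate_external_inputs(3, "default")
        b = generate_external_inputs(3, "default")
        np.testing.assert_array_equal(a.all_cause_mortality, b.all_cause_mortality)
        np.testing.assert_array_equal(a.incidence_smoker, b.incidence_smoker)

    def test_seed_changes_tables(self):
        a = generate_external_inputs(3, "default")
        b = generate_external_inputs(4, "default")
        assert not np.array_equal(a.all_cause_mortality, b.all_cause_mortality)

    def test_validity_invariants(self):
        for scenario in available_scenarios():
            ext = generate_external_inputs(0, scenario)
            ext.validate()
            assert np.all(ext.all_cause_mortality >= 0)
            assert np.all(np.diff(ext.all_cause_mortality, axis=0) >= -1e-15)
            np.testing.assert_allclose(ext.p_smoker + ext.p_former + ext.p_non, 1.0)

    def test_default_gradients_run_in_conventional_direction(self, externals):
        s = externals.opportunity_cost_shares
        h = externals.baseline_qale
        assert s[0] > s[4]          # opportunity costs fall on the deprived
        assert h[0] < h[4]          # deprived have lower baseline health
        # most deprived quintile faces the highest mortality at every age
        assert np.all(externals.all_cause_mortality[:, 0] >= externals.all_cause_mortality[:, 4])

    def test_flat_scenario_removes_gradients(self, flat_externals):
        assert np.ptp(flat_externals.opportunity_cost_shares) == 0.0
        assert np.ptp(flat_externals.baseline_qale) == 0.0
        assert np.ptp(flat_externals.all_cause_mortality, axis=1).max() == 0.0
        assert np.ptp(flat_externals.p_smoker, axis=1).max() == 0.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            generate_external_inputs(0, "nope")

    def test_tidy_frames(self, externals):
        mf = externals.mortality_frame()
        assert mf.shape == (83, 5)
        inc = externals.incidence_frame()
        assert set(inc["status"]) == {"smoker", "former"}


class TestFixtureBooks:
    def test_england_printed_parameters_verbatim(self, england_book):
        e = england_book.entries
        assert e["prevalence_imd1"].params == {"alpha": 2441.0, "beta": 11775.0}
        assert e["quit_rate_varenicline"].params == {"alpha": 6.0, "beta": 25.0}
        assert e["quit_rate_ecigarette"].params == {"alpha": 13.0, "beta": 87.0}
        assert e["rr_quit_imd2"].params == {"lm": 0.297, "lv": 0.168}
        assert e["uptake_imd1"].params == {"alpha": 96.0, "beta": 2284.0}

    def test_england_population_constants(self, england_book):
        assert england_book.population.size == 42_994_944
        assert england_book.population.quintile_shares == (0.2,) * 5
        assert england_book.settings.threshold_k == 20_000.0
        assert england_book.settings.discount_rate == 0.035
        assert england_book.settings.background_quit_rate == 0.02

    def test_york_prevalence_moment_matched_from_ci(self):
        book = fixture_parameter_book("york")
        spec = book.entries["prevalence_imd1"]
        assert spec.family == "beta"
        assert spec.mean == pytest.approx(0.1691, abs=1e-9)
        assert spec.sd == pytest.approx((0.2196 - 0.1186) / (2 * 1.96), rel=1e-3)
        assert book.population.size == 207_000

    def test_local_books_inherit_national_inputs(self):
        york = fixture_parameter_book("york")
        england = fixture_parameter_book("england")
        assert york.entries["quit_rate_varenicline"] == england.entries["quit_rate_varenicline"]
        assert york.entries["uptake_imd3"] == england.entries["uptake_imd3"]
        assert york.entries["prevalence_imd3"] != england.entries["prevalence_imd3"]

    def test_sheffield_more_deprived_higher_prevalence_than_york(self):
        york = fixture_parameter_book("york")
        sheffield = fixture_parameter_book("sheffield")
        assert sheffield.population.quintile_shares[0] > york.population.quintile_shares[0]
        for q in range(1, 6):
            assert (
                sheffield.entries[f"prevalence_imd{q}"].mean
                > york.entries[f"prevalence_imd{q}"].mean
            )

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            fixture_parameter_book("paris")

    def test_book_round_trip_is_exact(self, england_book, tmp_path):
        path = tmp_path / "book.yaml"
        save_book(england_book, path)
        again = load_book(path)
        assert set(again.entries) == set(england_book.entries)
        for name, spec in england_book.entries.items():
            assert again.entries[name].family == spec.family
            for k, v in spec.params.items():
                assert again.entries[name].params[k] == v
        np.testing.assert_array_equal(
            np.asarray(again.hrqol.params["cov"]), np.asarray(england_book.hrqol.params["cov"])
        )


class TestHRQoLCovariance:
    def test_exchangeable_structure(self):
        spec = build_hrqol_covariance({"a": 1.0, "b": -0.5}, rho=0.2)
        cov = np.asarray(spec.params["cov"])
        assert cov[0, 0] == pytest.approx(0.1**2)
        assert cov[0, 1] == pytest.approx(0.2 * 0.1 * 0.05)

    def test_floor_applies_to_small_coefficients(self):
        spec = build_hrqol_covariance({"tiny": 0.001}, se_floor=0.005)
        assert np.sqrt(spec.params["cov"][0][0]) == pytest.approx(0.005)

    def test_positive_definite(self, england_book):
        cov = np.asarray(england_book.hrqol.params["cov"])
        assert np.linalg.eigvalsh(cov).min() > 0


class TestFlattenedBook:
    def test_quintile_quantities_pinned(self, england_book):
        flat = flatten_book(england_book)
        for q in range(1, 6):
            assert flat.entries[f"rr_quit_imd{q}"].params["value"] == 1.0
            assert flat.entries[f"rr_disease_imd{q}"].params["value"] == 1.0
        prevs = {flat.entries[f"prevalence_imd{q}"].params["value"] for q in range(1, 6)}
        assert len(prevs) == 1

    def test_imd_utility_coefficients_zeroed(self, england_book):
        flat = flatten_book(england_book)
        names = flat.hrqol.params["names"]
        mean = np.asarray(flat.hrqol.params["mean"])
        for i, n in enumerate(names):
            if n.startswith("imd"):
                assert mean[i] == 0.0

    def test_non_quintile_uncertainty_preserved(self, england_book):
        flat = flatten_book(england_book)
        assert flat.entries["quit_rate_varenicline"] == england_book.entries["quit_rate_varenicline"]


class TestToyProblems:
    def test_metadata_closed_form_at_zero_mean(self):
        pm = dcea.toy_normal_decision_problem(0.0, 2.0, 100, seed=0)
        assert pm.metadata["analytic_evpi"] == pytest.approx(2.0 / np.sqrt(2 * np.pi))

    def test_vanishing_uncertainty_vanishing_value(self):
        assert dcea.normal_toy_evpi(1.0, 1e-9) < 1e-9

    def test_payoff_layout(self):
        pm = dcea.toy_normal_decision_problem(1.0, 1.0, 50, seed=1)
        assert pm.payoffs.shape == (50, 2)
        np.testing.assert_array_equal(pm.payoffs[:, 0], 0.0)
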