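import numpy as np
import pytest

import dcea
from dcea.parameters import DISEASES, HRQOL_COEF_NAMES, ParameterSample


@pytest.fixture(scope="session")
def england_book():
    return dcea.fixture_parameter_book("england")


@pytest.fixture(scope="session")
def externals():
    return dcea.generate_external_inputs(0, "default")


@pytest.fixture(scope="session")
def flat_externals():
    return dcea.generate_external_inputs(0, "flat")


@pytest.fixture(scope="session")
def mean_sample(england_book):
    return dcea.sample_at_means(england_book)


@pytest.fixture(scope="session")
def small_psa(england_book, externals):
    return dcea.run_psa(england_book, externals, n=120, seed=11)


def make_sample(**overrides) -> ParameterSample:
    """Hand-built parameter sample with neutral defaults, for oracle tests."""
    values = {}
    for q in range(1, 6):
        values[f"prevalence_imd{q}"] = 0.15
        values[f"uptake_imd{q}"] = 0.10
        values[f"rr_disease_imd{q}"] = 1.0
        values[f"rr_quit_imd{q}"] = 1.0
    for band in ("35_44", "45_54", "55_64", "65_74", "75plus"):
        values[f"rr_death_svn_{band}"] = 1.0
    values["rr_death_svf"] = 1.0
    values["quit_rate_varenicline"] = 0.19
    values["quit_rate_ecigarette"] = 0.13
    values["cost_intervention_varenicline"] = 0.0
    values["cost_intervention_ecigarette"] = 0.0
    for d in DISEASES:
        values[f"cost_{d}"] = 0.0
        values[f"disutility_{d}"] = 0.0
    for c in HRQOL_COEF_NAMES:
        values[f"hrqol_{c}"] = 0.0
    values["hrqol_constant"] = 1.0
    values.update(overrides)
    s = ParameterSample(values)
    s.truncation_count = 0
    return s


def make_externals(
    mortality: float = 0.0,
    incidence: float = 0.0,
    qale=(62.0, 65.0, 68.0, 71.0, 74.0),
    shares=(0.3, 0.25, 0.2, 0.15, 0.1),
    epsilon: float = 2.0,
) -> dcea.ExternalInputs:
    """Minimal constant external tables for closed-form oracle tests."""
    ages = np.arange(18, 101)
    A = ages.shape[0]
    return dcea.ExternalInputs(
        ages=ages,
        all_cause_mortality=np.full((A, 5), mortality),
        p_smoker=np.full((A, 5), 0.2),
        p_former=np.full((A, 5), 0.3),
        p_non=np.full((A, 5), 0.5),
        incidence_smoker=np.full((A, 6), incidence),
        incidence_former=np.full((A, 6), incidence / 2 if incidence else 0.0),
        baseline_qale=np.asarray(qale, dtype=float),
        opportunity_cost_shares=np.asarray(shares, dtype=float),
        inequality_aversion=epsilon,
        scenario="test",
    )
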