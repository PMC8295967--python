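"""Monte Carlo engine: determinism, common random numbers, summaries."""

import numpy as np
import pandas as pd
import pytest

import dcea
from dcea.markov import ModelSettings, _all_per_smoker_outcomes, population_arm_outcomes
from dcea.equity import EquitySettings, compare_outcomes
from dcea.psa import PSAResult, decision_probabilities, psa_summary_table, run_psa

from test_parameters import all_fixed_copy


def toy_psa(outputs: dict, n: int) -> PSAResult:
    out = pd.DataFrame(outputs)
    comparisons = sorted({c.split(":")[0] for c in out.columns})
    return PSAResult(
        inputs=pd.DataFrame({"x": np.zeros(n)}),
        outputs=out,
        comparisons=tuple(comparisons),
        seed=0,
        n_iterations=n,
    )


class TestRunPSA:
    def test_all_fixed_book_reproduces_base_case(self, england_book, externals):
        fixed = all_fixed_copy(england_book)
        psa = run_psa(fixed, externals, n=1, seed=0)
        bc = dcea.base_case(england_book, externals)
        for comp in psa.comparisons:
            assert psa.output(comp, "inhb")[0] == pytest.approx(bc.loc[comp, "inhb"], rel=1e-9)
            assert psa.output(comp, "delta")[0] == pytest.approx(bc.loc[comp, "delta"], rel=1e-6)

    def test_same_seed_bitwise_identical(self, england_book, externals):
        a = run_psa(england_book, externals, n=15, seed=5)
        b = run_psa(england_book, externals, n=15, seed=5)
        assert a.outputs.equals(b.outputs)
        assert a.inputs.equals(b.inputs)

    def test_different_seeds_differ(self, england_book, externals):
        a = run_psa(england_book, externals, n=5, seed=5)
        b = run_psa(england_book, externals, n=5, seed=6)
        assert not a.outputs.equals(b.outputs)

    def test_aligned_matrices_and_no_missing(self, small_psa):
        assert len(small_psa.inputs) == len(small_psa.outputs) == small_psa.n_iterations
        assert not small_psa.inputs.isna().any().any()
        assert not small_psa.outputs.isna().any().any()

    def test_invalid_arguments_rejected(self, england_book, externals):
        with pytest.raises(ValueError):
            run_psa(england_book, externals, n=0)
        with pytest.raises(ValueError):
            run_psa(england_book, externals, comparisons=[("magic_vs_none", "magic", "none")], n=1)

    def test_common_random_numbers_zero_self_increment(self, england_book, externals):
        rng = np.random.default_rng(2)
        settings = ModelSettings.from_book_settings(england_book.settings)
        ext = externals
        equity = EquitySettings.from_externals(ext, england_book.population, 20000.0)
        for _ in range(3):
            sample = dcea.draw_sample(england_book, rng)
            per = _all_per_smoker_outcomes(sample, ext, settings)
            out = population_arm_outcomes(
                sample, ext, england_book.population, "varenicline", settings, per_smoker=per
            )
            res = compare_outcomes(out, out, equity, label="self")
            assert res.inhb == 0.0
            assert res.delta == 0.0


class TestDecisionProbabilities:
    def test_counting_example(self):
        psa = toy_psa({"varenicline_vs_none:inhb": [1.0, -1, 2, -3],
                       "varenicline_vs_none:delta": [1.0, -1, 2, -3],
                       "varenicline_vs_none:iede": [0.0] * 4}, 4)
        probs = decision_probabilities(psa)
        assert probs.loc["varenicline_vs_none", "p_inhb_positive"] == 0.5
        assert probs.loc["varenicline_vs_none", "p_inhb_positive_se"] == pytest.approx(0.25)

    def test_all_positive_gives_certainty(self):
        psa = toy_psa({"ecigarette_vs_none:inhb": np.ones(50),
                       "ecigarette_vs_none:delta": np.ones(50),
                       "ecigarette_vs_none:iede": np.ones(50)}, 50)
        probs = decision_probabilities(psa)
        assert probs.loc["ecigarette_vs_none", "p_inhb_positive"] == 1.0
        assert probs.loc["ecigarette_vs_none", "p_inhb_positive_se"] == 0.0

    def test_symmetric_outputs_near_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10_000)
        psa = toy_psa({"varenicline_vs_ecigarette:inhb": x,
                       "varenicline_vs_ecigarette:delta": x,
                       "varenicline_vs_ecigarette:iede": x}, x.size)
        p = decision_probabilities(psa).loc["varenicline_vs_ecigarette", "p_inhb_positive"]
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / x.size)

    def test_invariant_to_iteration_order(self, small_psa):
        probs = decision_probabilities(small_psa)
        rng = np.random.default_rng(1)
        perm = rng.permutation(small_psa.n_iterations)
        shuffled = PSAResult(
            inputs=small_psa.inputs.iloc[perm].reset_index(drop=True),
            outputs=small_psa.outputs.iloc[perm].reset_index(drop=True),
            comparisons=small_psa.comparisons,
            seed=small_psa.seed,
            n_iterations=small_psa.n_iterations,
        )
        pd.testing.assert_frame_equal(probs, decision_probabilities(shuffled))


class TestSummaryTable:
    def test_constant_outputs_degenerate_interval(self):
        psa = toy_psa({"varenicline_vs_none:inhb": np.full(20, 7.0),
                       "varenicline_vs_none:delta": np.full(20, -2.0),
                       "varenicline_vs_none:iede": np.full(20, 5.0)}, 20)
        t = psa_summary_table(psa)
        row = t.loc["varenicline_vs_none"]
        assert row["mean_inhb"] == 7.0
        assert row["inhb_p2.5"] == row["inhb_p97.5"] == 7.0
        assert row["p_inequality_reduced_pct"] == 0.0

    def test_normal_percentiles(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10_000)
        psa = toy_psa({"varenicline_vs_none:inhb": x,
                       "varenicline_vs_none:delta": x,
                       "varenicline_vs_none:iede": x}, x.size)
        row = psa_summary_table(psa).loc["varenicline_vs_none"]
        assert row["inhb_p2.5"] == pytest.approx(-1.96, abs=0.1)
        assert row["inhb_p97.5"] == pytest.approx(1.96, abs=0.1)

    def test_row_per_comparison(self, small_psa):
        t = psa_summary_table(small_psa)
        assert len(t) == len(small_psa.comparisons)

    def test_probabilities_printed_to_two_decimals(self, small_psa):
        t = psa_summary_table(small_psa)
        for col in ("p_inhb_positive_pct", "p_inequality_reduced_pct"):
            assert (t[col] == t[col].round(2)).all()
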