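"""Probabilistic sensitivity analysis: Monte Carlo propagation of uncertainty.

Each iteration draws one joint :class:`~dcea.parameters.ParameterSample`,
runs the cohort model for all three arms under that common sample (common
random numbers, so within-iteration comparisons are exact differences), and
records population iNHB, iEDE and the inequality impact for every requested
pairwise comparison, alongside the sampled input vector.  The aligned
iteration x input and iteration x output matrices are the contract consumed
by the value-of-information and ANCOVA modules (SAVI-style layout: one
header row of parameter names, one row per iteration).

Reproducibility: a root seed spawns one independent substream per iteration
(`numpy` ``SeedSequence.spawn``), so results are bitwise identical for a
given (seed, n) and invariant to how iterations would be distributed across
workers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equity import EquitySettings, compare_outcomes
from .external import ExternalInputs
from .markov import ModelSettings, _all_per_smoker_outcomes, population_arm_outcomes
from .parameters import ARMS, ParameterBook, ParameterSample, draw_sample, sample_at_means

logger = logging.getLogger(__name__)

__all__ = [
    "COMPARISONS",
    "PSAResult",
    "run_psa",
    "base_case",
    "decision_probabilities",
    "psa_summary_table",
    "scatter_frame",
]

#: pairwise comparisons: (label, arm a, arm b); results are a minus b
COMPARISONS = (
    ("varenicline_vs_none", "varenicline", "none"),
    ("ecigarette_vs_none", "ecigarette", "none"),
    ("varenicline_vs_ecigarette", "varenicline", "ecigarette"),
)


@dataclass
class PSAResult:
    """Aligned iteration x input and iteration x output matrices."""

    inputs: pd.DataFrame     # one column per sampled scalar
    outputs: pd.DataFrame    # columns '<comparison>:inhb' / ':iede' / ':delta'
    comparisons: tuple
    seed: int
    n_iterations: int
    truncation_count: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.inputs) != len(self.outputs):
            raise ValueError("input and output matrices must have equal row counts")
        if self.outputs.isna().any().any() or self.inputs.isna().any().any():
            raise ValueError("PSA matrices must not contain missing values")

    def output(self, comparison: str, quantity: str) -> np.ndarray:
        return self.outputs[f"{comparison}:{quantity}"].to_numpy()


def _evaluate_sample(
    sample: ParameterSample,
    externals: ExternalInputs,
    population,
    settings: ModelSettings,
    equity: EquitySettings,
    comparisons,
) -> dict:
    per_smoker = _all_per_smoker_outcomes(sample, externals, settings)
    arm_outcomes = {
        arm: population_arm_outcomes(
            sample, externals, population, arm, settings, per_smoker=per_smoker
        )
        for arm in ARMS
    }
    row = {}
    for label, a, b in comparisons:
        res = compare_outcomes(arm_outcomes[a], arm_outcomes[b], equity, label=label)
        row[f"{label}:inhb"] = res.inhb
        row[f"{label}:iede"] = res.iede
        row[f"{label}:delta"] = res.delta
    return row


def run_psa(
    book: ParameterBook,
    externals: ExternalInputs,
    population=None,
    comparisons=COMPARISONS,
    n: int = 1000,
    seed: int = 42,
    epsilon: float | None = None,
) -> PSAResult:
    """Run the full Monte Carlo uncertainty analysis.

    Any iteration failure aborts the run with the iteration index and the
    offending sampled values logged.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    labels = {c[0] for c in comparisons}
    known = {c[0] for c in COMPARISONS}
    if not labels <= known:
        raise ValueError(f"unknown comparisons {labels - known}")
    book.validate()
    if population is None:
        population = book.population
    settings = ModelSettings.from_book_settings(book.settings)
    equity = EquitySettings.from_externals(
        externals, population, book.settings.threshold_k, epsilon=epsilon
    )

    input_names = book.sampled_names()
    children = np.random.SeedSequence(seed).spawn(n)
    in_rows = np.empty((n, len(input_names)))
    out_rows = []
    truncations = 0
    for i in range(n):
        rng = np.random.default_rng(children[i])
        sample = draw_sample(book, rng)
        truncations += sample.truncation_count
        try:
            row = _evaluate_sample(sample, externals, population, settings, equity, comparisons)
        except Exception:
            logger.error(
                "PSA iteration %d failed; sampled values: %s",
                i,
                {k: sample[k] for k in input_names},
            )
            raise
        in_rows[i] = [sample[k] for k in input_names]
        out_rows.append(row)

    result = PSAResult(
        inputs=pd.DataFrame(in_rows, columns=input_names),
        outputs=pd.DataFrame(out_rows),
        comparisons=tuple(c[0] for c in comparisons),
        seed=seed,
        n_iterations=n,
        truncation_count=truncations,
        metadata={
            "region": population.name,
            "externals_scenario": externals.scenario,
            "externals_seed": externals.seed,
            "epsilon": equity.epsilon,
        },
    )
    return result


def base_case(
    book: ParameterBook,
    externals: ExternalInputs,
    population=None,
    comparisons=COMPARISONS,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Deterministic run with every input at its mean (one row per comparison)."""
    book.validate()
    if population is None:
        population = book.population
    settings = ModelSettings.from_book_settings(book.settings)
    equity = EquitySettings.from_externals(
        externals, population, book.settings.threshold_k, epsilon=epsilon
    )
    sample = sample_at_means(book)
    row = _evaluate_sample(sample, externals, population, settings, equity, comparisons)
    records = []
    for label, _, _ in comparisons:
        records.append(
            {
                "comparison": label,
                "inhb": row[f"{label}:inhb"],
                "iede": row[f"{label}:iede"],
                "delta": row[f"{label}:delta"],
            }
        )
    return pd.DataFrame(records).set_index("comparison")


def decision_probabilities(psa: PSAResult) -> pd.DataFrame:
    """P(iNHB > 0) and P(inequality reduced, iEDE > iNHB) per comparison.

    Empirical proportions with their binomial Monte Carlo standard errors
    sqrt(p (1-p) / n).
    """
    n = psa.n_iterations
    rows = []
    for label in psa.comparisons:
        p_h = float((psa.output(label, "inhb") > 0).mean())
        p_e = float((psa.output(label, "delta") > 0).mean())
        rows.append(
            {
                "comparison": label,
                "p_inhb_positive": p_h,
                "p_inhb_positive_se": float(np.sqrt(p_h * (1 - p_h) / n)),
                "p_inequality_reduced": p_e,
                "p_inequality_reduced_se": float(np.sqrt(p_e * (1 - p_e) / n)),
            }
        )
    return pd.DataFrame(rows).set_index("comparison")


def psa_summary_table(psa: PSAResult) -> pd.DataFrame:
    """Means, decision probabilities and 2.5/97.5 percentile intervals."""
    probs = decision_probabilities(psa)
    rows = []
    for label in psa.comparisons:
        inhb = psa.output(label, "inhb")
        delta = psa.output(label, "delta")
        rows.append(
            {
                "comparison": label,
                "mean_inhb": float(inhb.mean()),
                "inhb_p2.5": float(np.percentile(inhb, 2.5)),
                "inhb_p97.5": float(np.percentile(inhb, 97.5)),
                "mean_delta": float(delta.mean()),
                "delta_p2.5": float(np.percentile(delta, 2.5)),
                "delta_p97.5": float(np.percentile(delta, 97.5)),
                "p_inhb_positive_pct": round(100.0 * probs.loc[label, "p_inhb_positive"], 2),
                "p_inequality_reduced_pct": round(
                    100.0 * probs.loc[label, "p_inequality_reduced"], 2
                ),
            }
        )
    return pd.DataFrame(rows).set_index("comparison")


def scatter_frame(psa: PSAResult) -> pd.DataFrame:
    """Tidy (iteration, comparison, delta, inhb) table for equity-plane plots."""
    frames = []
    for label in psa.comparisons:
        frames.append(
            pd.DataFrame(
                {
                    "iteration": np.arange(psa.n_iterations),
                    "comparison": label,
                    "delta": psa.output(label, "delta"),
                    "inhb": psa.output(label, "inhb"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
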