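"""Toy decision problems with known answers, for oracle-backed testing.

The two-decision normal toy has a closed-form expected value of perfect
information: with incremental payoff X ~ Normal(mu, sigma) against a zero
comparator,

    EVPI = sigma * phi(mu/sigma) - |mu| * Phi(-|mu|/sigma)

(the unit normal loss integral), which the Monte Carlo estimator must
approach as n grows.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .voi import PayoffMatrix

__all__ = ["normal_toy_evpi", "toy_normal_decision_problem"]


def normal_toy_evpi(mu: float, sigma: float) -> float:
    """Closed-form EVPI of the two-decision normal toy (unit normal loss)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return 0.0
    z = abs(mu) / sigma
    return float(sigma * stats.norm.pdf(z) - abs(mu) * stats.norm.cdf(-z))


def toy_normal_decision_problem(
    mu: float, sigma: float, n: int, seed: int = 0
) -> PayoffMatrix:
    """Payoff matrix {0, X_i} with X ~ Normal(mu, sigma), analytic EVPI attached."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    x = rng.normal(mu, sigma, size=n)
    return PayoffMatrix(
        payoffs=np.column_stack([np.zeros(n), x]),
        decisions=("comparator", "intervention"),
        framing="health",
        metadata={
            "analytic_evpi": normal_toy_evpi(mu, sigma),
            "mu": mu,
            "sigma": sigma,
            "incremental": x,
        },
    )
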