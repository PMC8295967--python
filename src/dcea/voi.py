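"""Value of information: EVPI and regression-based EVPPI.

The decision problem is framed as a payoff matrix (iterations x decisions)
on a common monetary scale.  Two framings are built from PSA output for a
pairwise comparison against comparator payoffs of zero:

* health framing — payoffs {0, iNHB x k}: the value of knowing which
  intervention improves overall health;
* equity framing — payoffs {0, (iEDE - iNHB) x k}: the value of knowing
  which intervention reduces health inequality.

EVPI is the usual Monte Carlo estimator
``mean_i[max_d payoff(i, d)] - max_d[mean_i payoff(i, d)]``.  EVPPI for a
parameter subset follows the nonparametric-regression approach popularised
by the SAVI platform: the conditional expectation of each decision's payoff
given the subset is estimated by a flexible smooth regression (an additive
cubic-spline fit for up to four parameters, a Gaussian-process fit beyond
that), and the EVPI formula is applied to the fitted values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PayoffMatrix",
    "evpi_from_payoffs",
    "evppi_regression",
    "population_scale_monetize",
    "comparison_payoffs",
    "default_parameter_groups",
    "voi_report",
]

FRAMINGS = ("health", "equity")


@dataclass
class PayoffMatrix:
    """Iterations x decisions payoffs on a common scale."""

    payoffs: np.ndarray
    decisions: tuple
    framing: str = "health"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.payoffs = np.asarray(self.payoffs, dtype=float)
        if self.payoffs.ndim != 2 or self.payoffs.shape[1] < 2:
            raise ValueError("payoffs must be (n, d) with at least two decisions")
        if not np.all(np.isfinite(self.payoffs)):
            raise ValueError("payoffs must be finite")
        if len(self.decisions) != self.payoffs.shape[1]:
            raise ValueError("decision labels must match the payoff columns")

    @property
    def n(self) -> int:
        return self.payoffs.shape[0]


def evpi_from_payoffs(payoffs: PayoffMatrix) -> float:
    """Expected value of perfect information from a payoff matrix.

    E[max_d payoff] - max_d E[payoff]; non-negative by Jensen's inequality
    (up to zero, exactly, when one decision dominates in every iteration).
    """
    p = payoffs.payoffs
    if p.shape[0] < 2:
        raise ValueError("EVPI needs at least two iterations")
    return float(p.max(axis=1).mean() - p.mean(axis=0).max())


def _fit_conditional_means(
    y: np.ndarray, X: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Smooth estimate of E[y | X] at the observed points."""
    if np.ptp(y) == 0.0:
        return np.full_like(y, y[0])
    n, k = X.shape
    # drop constant columns (fixed reference parameters)
    keep = np.ptp(X, axis=0) > 0
    if not keep.any():
        return np.full_like(y, y.mean())
    X = X[:, keep]
    k = X.shape[1]
    if k <= 4:
        from sklearn.linear_model import LinearRegression
        from sklearn.preprocessing import SplineTransformer

        basis = SplineTransformer(n_knots=6, degree=3, include_bias=False)
        Z = basis.fit_transform(X)  # additive: per-column bases, concatenated
        model = LinearRegression().fit(Z, y)
        return model.predict(Z)
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    n_fit = min(n, 400)
    idx = rng.choice(n, size=n_fit, replace=False) if n > n_fit else np.arange(n)
    mu, sd = X.mean(axis=0), np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Xs = (X - mu) / sd
    # lengthscales bounded away from interpolation; nugget free to dominate
    # when the subset carries no signal
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3)) * RBF(np.full(k, 10.0), (5e-1, 1e3))
        + WhiteKernel(1.0, (1e-6, 1e2))
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, alpha=1e-10)
        gp.fit(Xs[idx], y[idx])
    return gp.predict(Xs)


def evppi_regression(
    payoffs: PayoffMatrix,
    inputs: pd.DataFrame,
    subset: list[str] | str,
    seed: int = 0,
) -> tuple[float, float]:
    """EVPPI for a parameter subset, with a standard-error heuristic.

    Returns ``(evppi, se)``.  The point estimate is the EVPI formula applied
    to the fitted conditional-mean payoffs, clipped at zero; the standard
    error is the Monte Carlo error of the per-iteration fitted regret,
    sd(max_d ghat - ghat_chosen)/sqrt(n) — a heuristic, not a full account
    of regression uncertainty.
    """
    if isinstance(subset, str):
        subset = [subset]
    if not subset:
        raise ValueError("subset must name at least one parameter")
    missing = [c for c in subset if c not in inputs.columns]
    if missing:
        raise ValueError(f"subset columns absent from inputs: {missing}")
    X = inputs[list(subset)].to_numpy(dtype=float)
    if X.shape[0] != payoffs.n:
        raise ValueError("inputs and payoffs must have aligned iterations")
    if payoffs.n < 100:
        logger.warning("EVPPI regression on only %d iterations; estimates will be noisy", payoffs.n)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < min(X.shape[1], X.shape[0]):
        logger.warning("rank-deficient parameter subset; proceeding on pruned columns")

    rng = np.random.default_rng(seed)
    ghat = np.column_stack(
        [_fit_conditional_means(payoffs.payoffs[:, d], X, rng) for d in range(payoffs.payoffs.shape[1])]
    )
    best = ghat.max(axis=1)
    chosen = ghat.mean(axis=0).argmax()
    evppi = float(best.mean() - ghat[:, chosen].mean())
    regret = best - ghat[:, chosen]
    se = float(regret.std(ddof=1) / np.sqrt(payoffs.n))
    return max(evppi, 0.0), se


def population_scale_monetize(value: float, k: float, population_factor: float = 1.0) -> float:
    """Convert a QALY-scale information value to pounds (pure scaling)."""
    if k <= 0:
        raise ValueError("threshold k must be positive")
    return float(value) * k * population_factor


def comparison_payoffs(psa, comparison: str, framing: str = "health") -> PayoffMatrix:
    """Two-decision payoff matrix {comparator: 0, intervention: outcome x k}.

    ``psa`` is a :class:`~dcea.psa.PSAResult`; the outcome is population iNHB
    (health framing) or the inequality impact iEDE - iNHB (equity framing),
    monetised at the threshold recorded with the PSA metadata's book (the
    caller passes k through :func:`voi_report`; here payoffs stay in QALYs
    unless a threshold is supplied in the PSA metadata).
    """
    if framing not in FRAMINGS:
        raise ValueError(f"framing must be one of {FRAMINGS}")
    quantity = "inhb" if framing == "health" else "delta"
    x = psa.output(comparison, quantity)
    payoffs = np.column_stack([np.zeros_like(x), x])
    return PayoffMatrix(
        payoffs=payoffs,
        decisions=("comparator", "intervention"),
        framing=framing,
        metadata={"comparison": comparison, "scale": "QALYs"},
    )


def default_parameter_groups(input_columns) -> dict:
    """Named parameter groups mirroring the sensitivity-report axis."""
    prefixes = {
        "smoking_prevalence": ("prevalence_",),
        "rr_death": ("rr_death_",),
        "rr_disease": ("rr_disease_",),
        "hrqol": ("hrqol_",),
        "average_quit_rates": ("quit_rate_",),
        "rr_quit_imd": ("rr_quit_",),
        "uptake_imd": ("uptake_",),
        "costs": ("cost_",),
        "disutilities": ("disutility_",),
    }
    groups = {}
    for name, pres in prefixes.items():
        cols = [c for c in input_columns if c.startswith(pres)]
        if cols:
            groups[name] = cols
    return groups


def voi_report(
    psa,
    comparison: str = "varenicline_vs_ecigarette",
    threshold_k: float = 20000.0,
    groups: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """EVPI plus per-group EVPPI for both framings, monetised at k."""
    if groups is None:
        groups = default_parameter_groups(psa.inputs.columns)
    rows = []
    for framing in FRAMINGS:
        pm = comparison_payoffs(psa, comparison, framing)
        evpi = evpi_from_payoffs(pm)
        rows.append(
            {
                "framing": framing,
                "group": "all (EVPI)",
                "value_qalys": evpi,
                "value_gbp": population_scale_monetize(evpi, threshold_k),
                "se_gbp": np.nan,
            }
        )
        for gname, cols in groups.items():
            evppi, se = evppi_regression(pm, psa.inputs, cols, seed=seed)
            evppi = min(evppi, evpi)  # perfect partial information cannot beat EVPI
            rows.append(
                {
                    "framing": framing,
                    "group": gname,
                    "value_qalys": evppi,
                    "value_gbp": population_scale_monetize(evppi, threshold_k),
                    "se_gbp": population_scale_monetize(se, threshold_k),
                }
            )
    return pd.DataFrame(rows)
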