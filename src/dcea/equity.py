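"""Equity metrics: net health benefit, Atkinson EDE health, inequality impact.

Two headline statistics summarise each pairwise comparison of arms:

* population incremental net health benefit (iNHB) — incremental QALYs minus
  the health forgone elsewhere when the incremental cost displaces other
  spending.  Total incremental cost is pooled, converted to forgone health at
  the threshold k, and distributed across deprivation quintiles by the
  opportunity-cost shares s_q:  iNHB_q = dQALY_q - C s_q / k.
* inequality impact (iEDE - iNHB) — the change in population
  equally-distributed-equivalent (EDE) health beyond the change in total
  health.  EDE uses the Atkinson social welfare function with inequality
  aversion epsilon: for epsilon != 1, EDE = (sum_q w_q h_q^(1-eps))^(1/(1-eps));
  for epsilon = 1 the weighted geometric mean.  Per-quintile iNHB is diluted
  over the whole quintile population before being added to baseline
  quality-adjusted life expectancy, so a zero-aversion analysis has zero
  inequality impact by construction.

A comparison is placed on the health equity impact plane by the signs of
iNHB (overall health, vertical axis) and iEDE - iNHB (inequality impact,
horizontal axis): "win-win" improves both, "win-lose" improves health but
worsens inequality, etc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .external import ExternalInputs
from .parameters import PopulationSpec

__all__ = [
    "EquitySettings",
    "ComparisonResult",
    "incremental_net_health_benefit",
    "atkinson_ede",
    "incremental_ede",
    "equity_impact_summary",
    "compare_outcomes",
]

EPSILON_SWEEP = (0.0, 1.0, 2.0, 5.0, 10.95, 20.0)


@dataclass(frozen=True)
class EquitySettings:
    """Threshold, opportunity-cost shares, aversion, baseline health, populations."""

    threshold_k: float
    opportunity_cost_shares: tuple     # (5,) sums to 1
    epsilon: float
    baseline_qale: tuple               # (5,) QALYs per person
    quintile_populations: tuple        # (5,) persons

    def __post_init__(self):
        if self.threshold_k <= 0:
            raise ValueError("threshold k must be positive")
        s = np.asarray(self.opportunity_cost_shares, dtype=float)
        if abs(s.sum() - 1.0) > 1e-9:
            raise ValueError(f"opportunity-cost shares sum to {s.sum()}, not 1")
        if self.epsilon < 0:
            raise ValueError("inequality aversion must be non-negative")
        if np.any(np.asarray(self.baseline_qale) <= 0):
            raise ValueError("baseline QALE must be positive")

    @classmethod
    def from_externals(
        cls,
        externals: ExternalInputs,
        population: PopulationSpec,
        threshold_k: float,
        epsilon: float | None = None,
    ) -> "EquitySettings":
        return cls(
            threshold_k=threshold_k,
            opportunity_cost_shares=tuple(externals.opportunity_cost_shares),
            epsilon=externals.inequality_aversion if epsilon is None else epsilon,
            baseline_qale=tuple(externals.baseline_qale),
            quintile_populations=tuple(population.quintile_sizes),
        )


@dataclass
class ComparisonResult:
    """iNHB, iEDE and inequality impact for one pairwise comparison."""

    comparison: str
    inhb_q: np.ndarray      # (5,) per-quintile iNHB, QALYs
    inhb: float             # total iNHB, QALYs
    iede: float             # incremental EDE, QALYs
    delta: float            # iEDE - iNHB (inequality impact)
    quadrant: str

    def as_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            **{f"inhb_imd{q}": float(self.inhb_q[q - 1]) for q in range(1, 6)},
            "inhb": self.inhb,
            "iede": self.iede,
            "delta": self.delta,
            "quadrant": self.quadrant,
        }


def incremental_net_health_benefit(
    delta_qalys: np.ndarray, delta_costs: np.ndarray, settings: EquitySettings
) -> tuple[np.ndarray, float]:
    """Per-quintile and total iNHB from incremental QALYs and costs.

    Incremental costs are pooled across quintiles before conversion to
    forgone health, because funding displacement happens at the level of the
    total budget; the forgone health then falls on quintiles by s_q.
    """
    dq = np.asarray(delta_qalys, dtype=float)
    dc = np.asarray(delta_costs, dtype=float)
    if dq.shape != (5,) or dc.shape != (5,):
        raise ValueError("per-quintile inputs must have five entries")
    s = np.asarray(settings.opportunity_cost_shares, dtype=float)
    total_cost = dc.sum()
    inhb_q = dq - total_cost * s / settings.threshold_k
    return inhb_q, float(inhb_q.sum())


def atkinson_ede(levels, weights, epsilon: float) -> float:
    """Atkinson equally-distributed-equivalent of a health distribution.

    epsilon = 0 gives the weighted mean; epsilon = 1 the weighted geometric
    mean; epsilon = 2 the weighted harmonic mean.  EDE <= mean, with equality
    iff all levels are equal (for epsilon > 0).
    """
    h = np.asarray(levels, dtype=float)
    w = np.asarray(weights, dtype=float)
    if h.shape != w.shape:
        raise ValueError("levels and weights must have the same shape")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    if epsilon < 0:
        raise ValueError("inequality aversion must be non-negative")
    if np.any(h < 0):
        raise ValueError("health levels must be non-negative")
    if epsilon >= 1.0 and np.any(h <= 0):
        raise ValueError("health levels must be strictly positive for epsilon >= 1")
    # exactly equal distributions return the common level, avoiding power-mean
    # rounding that population scaling (N ~ 1e7) would otherwise amplify
    if np.ptp(h) == 0.0:
        return float(h.flat[0])
    if epsilon == 0.0:
        return float(w @ h)
    if epsilon == 1.0:
        return float(np.exp(w @ np.log(h)))
    return float((w @ h ** (1.0 - epsilon)) ** (1.0 / (1.0 - epsilon)))


def incremental_ede(inhb_q: np.ndarray, settings: EquitySettings) -> float:
    """Population incremental EDE from per-quintile iNHB.

    Each quintile's population iNHB is diluted over the quintile population
    and added to the baseline per-person QALE; iEDE is the population-scaled
    change in EDE health.
    """
    inhb_q = np.asarray(inhb_q, dtype=float)
    n_q = np.asarray(settings.quintile_populations, dtype=float)
    h = np.asarray(settings.baseline_qale, dtype=float)
    h_post = h + inhb_q / n_q
    for q in range(5):
        if h_post[q] <= 0:
            raise ValueError(f"post-intervention health non-positive in IMD{q + 1}")
    n = n_q.sum()
    w = n_q / n
    return float(
        n * (atkinson_ede(h_post, w, settings.epsilon) - atkinson_ede(h, w, settings.epsilon))
    )


def equity_impact_summary(inhb: float, iede: float) -> tuple[float, str]:
    """Inequality impact and health-equity-impact-plane quadrant label."""
    if not (np.isfinite(inhb) and np.isfinite(iede)):
        raise ValueError("iNHB and iEDE must be finite")
    delta = iede - inhb
    if inhb == 0.0 or delta == 0.0:
        return delta, "boundary"
    vert = "win" if inhb > 0 else "lose"
    horiz = "win" if delta > 0 else "lose"
    return delta, f"{vert}-{horiz}"


def compare_outcomes(
    outcome_a, outcome_b, settings: EquitySettings, label: str | None = None
) -> ComparisonResult:
    """Full comparison of two arms (a relative to b) on the equity plane."""
    dq = outcome_a.qalys - outcome_b.qalys
    dc = outcome_a.costs - outcome_b.costs
    inhb_q, inhb = incremental_net_health_benefit(dq, dc, settings)
    iede = incremental_ede(inhb_q, settings)
    delta, quadrant = equity_impact_summary(inhb, iede)
    return ComparisonResult(
        comparison=label or f"{outcome_a.arm}_vs_{outcome_b.arm}",
        inhb_q=inhb_q,
        inhb=inhb,
        iede=iede,
        delta=delta,
        quadrant=quadrant,
    )
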