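"""Three-state Markov cohort model of smoking cessation.

States are smoker, former smoker and dead.  The full cohort enters as
smokers at a given age; each annual cycle applies, in order, the quit
transition then state-specific mortality.  Former smokers never relapse.
Six smoking-related diseases (lung cancer, coronary heart disease, COPD,
myocardial infarction, stroke, asthma exacerbation) are modelled as
independent, memoryless events: each cycle the expected event count is
occupancy x incidence(age, status) x quintile disease relative risk, and
each event contributes a one-cycle cost and utility decrement.

Smoker mortality is derived from all-cause mortality by inverting the
population mixture: with status proportions (p_s, p_f, p_n) and relative
risks RR_svf (smokers v. former) and RR_svn (smokers v. nonsmokers),

    m_s = all_cause / (p_s + p_f / RR_svf + p_n / RR_svn),

so the population-weighted average of m_s, m_s/RR_svf and m_s/RR_svn
reproduces the all-cause rate exactly.

Accrual conventions: disease events, QALYs and costs use start-of-cycle
occupancy; the discount factor for cycle t (t = 0, 1, ...) is (1+r)^(-t);
there is no half-cycle correction; survivors at the age cap are censored.
Intervention unit costs apply in the first cycle of active arms only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .external import ExternalInputs
from .parameters import ARMS, DISEASES, BookSettings, ParameterSample

logger = logging.getLogger(__name__)

#: quintiles already warned about out-of-range utilities (avoids log floods)
_utility_warned: set = set()

__all__ = [
    "ModelSettings",
    "CohortTrace",
    "ArmOutcome",
    "smoker_mortality_rate",
    "annual_quit_probability",
    "run_cohort_trace",
    "per_smoker_lifetime_outcomes",
    "population_arm_outcomes",
]


@dataclass(frozen=True)
class ModelSettings:
    """Cycle, discounting and cohort-entry settings (annual cycles)."""

    discount_rate: float = 0.035
    background_quit_rate: float = 0.02
    age_cap: int = 100
    entry_age_min: int = 18
    entry_age_max: int = 75
    #: optional explicit entry-age weights (defaults to uniform)
    entry_age_weights: tuple | None = None

    def __post_init__(self):
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount rate must lie in [0, 1)")
        if not 18 <= self.entry_age_min <= self.entry_age_max <= 75:
            raise ValueError("entry ages must lie within [18, 75]")
        if self.age_cap <= self.entry_age_max:
            raise ValueError("age cap must exceed the oldest entry age")

    @classmethod
    def from_book_settings(cls, s: BookSettings) -> "ModelSettings":
        return cls(
            discount_rate=s.discount_rate,
            background_quit_rate=s.background_quit_rate,
            age_cap=s.age_cap,
            entry_age_min=s.entry_age_min,
            entry_age_max=s.entry_age_max,
        )

    @property
    def entry_ages(self) -> np.ndarray:
        return np.arange(self.entry_age_min, self.entry_age_max + 1)

    @property
    def entry_weights(self) -> np.ndarray:
        ages = self.entry_ages
        if self.entry_age_weights is None:
            return np.full(ages.shape[0], 1.0 / ages.shape[0])
        w = np.asarray(self.entry_age_weights, dtype=float)
        if w.shape != ages.shape:
            raise ValueError("entry_age_weights length must match the entry-age range")
        if w.sum() <= 0:
            raise ValueError("entry-age distribution must have positive mass")
        return w / w.sum()


@dataclass
class CohortTrace:
    """Per-cycle record of one quintile x arm cohort from a single entry age."""

    entry_age: int
    quintile: int
    arm: str
    cycles: np.ndarray          # (T,) cycle index 0..T-1
    smoker: np.ndarray          # (T,) start-of-cycle occupancy
    former: np.ndarray          # (T,)
    dead: np.ndarray            # (T,)
    events: np.ndarray          # (T, 6) expected disease events
    disc_qaly: np.ndarray       # (T,) discounted QALY accrual
    disc_cost: np.ndarray       # (T,) discounted cost accrual

    @property
    def total_qalys(self) -> float:
        return float(self.disc_qaly.sum())

    @property
    def total_costs(self) -> float:
        return float(self.disc_cost.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle export (one row per cycle x disease)."""
        base = pd.DataFrame(
            {
                "cycle": self.cycles,
                "age": self.entry_age + self.cycles,
                "smoker": self.smoker,
                "former": self.former,
                "dead": self.dead,
                "disc_qaly": self.disc_qaly,
                "disc_cost": self.disc_cost,
            }
        )
        ev = pd.DataFrame(self.events, columns=list(DISEASES))
        ev.insert(0, "cycle", self.cycles)
        long = ev.melt(id_vars="cycle", var_name="disease", value_name="events")
        return base.merge(long, on="cycle")

    def check_invariants(self, atol: float = 1e-9) -> None:
        occ = self.smoker + self.former + self.dead
        if not np.allclose(occ, 1.0, atol=atol):
            raise AssertionError("state occupancies do not sum to 1")
        if np.any(self.smoker < -atol) or np.any(self.former < -atol) or np.any(self.dead < -atol):
            raise AssertionError("negative state occupancy")
        if np.any(np.diff(self.dead) < -atol):
            raise AssertionError("dead occupancy decreased")


@dataclass
class ArmOutcome:
    """Population-scaled totals for one arm: per-quintile QALYs and costs."""

    arm: str
    qalys: np.ndarray                    # (5,) total discounted QALYs
    costs: np.ndarray                    # (5,) total discounted costs (GBP)
    per_smoker: dict = field(default_factory=dict)  # quintile -> (qaly, cost)


def smoker_mortality_rate(
    all_cause: float,
    p_smoker: float,
    p_former: float,
    p_non: float,
    rr_svf: float,
    rr_svn: float,
) -> float:
    """Annual mortality rate for smokers implied by the all-cause rate.

    Scalar reference form of the mixture inversion documented in the module
    docstring; the vectorised engine applies the same formula arraywise.
    """
    if not 0.0 <= all_cause < 1.0:
        raise ValueError("all-cause rate must lie in [0, 1)")
    if rr_svf <= 0 or rr_svn <= 0:
        raise ValueError("relative risks must be positive")
    denom = p_smoker + p_former / rr_svf + p_non / rr_svn
    if denom <= 0:
        raise ValueError("status proportions yield a non-positive denominator")
    return all_cause / denom


def annual_quit_probability(
    base_quit: float,
    rr_quit: float,
    is_first_cycle: bool = True,
    arm: str = "none",
    background_quit: float = 0.02,
) -> float:
    """Quit probability for one cycle.

    The first cycle of an active arm uses the intervention quit rate
    (``base_quit``); every other cycle — and every cycle of the
    no-intervention arm — uses the background quit rate.  Either way the rate
    is scaled by the quintile's relative risk of quitting and clamped to
    [0, 1] (clamps are logged).
    """
    if rr_quit < 0:
        raise ValueError("relative risk of quitting must be non-negative")
    base = base_quit if (is_first_cycle and arm != "none") else background_quit
    p = base * rr_quit
    if p > 1.0 or p < 0.0:
        logger.warning("quit probability %.4f clamped to [0, 1]", p)
        p = min(max(p, 0.0), 1.0)
    return p


def _quintile_tables(
    sample: ParameterSample, externals: ExternalInputs, quintile: int
) -> dict:
    """Per-age arrays (index = age 18..cap) for one quintile under one sample."""
    ages = externals.ages
    qi = quintile - 1
    rr_svf = sample.rr_death_svf
    rr_svn = sample.rr_death_svn_by_age(ages)
    denom = (
        externals.p_smoker[:, qi]
        + externals.p_former[:, qi] / rr_svf
        + externals.p_non[:, qi] / rr_svn
    )
    if np.any(denom <= 0):
        raise ValueError("status proportions yield a non-positive denominator")
    m_s = externals.all_cause_mortality[:, qi] / denom
    m_f = m_s / rr_svf
    m_s = np.minimum(m_s, 1.0)
    m_f = np.minimum(m_f, 1.0)

    # incidence representative of IMD3: scale by RR_q / RR_IMD3 so that the
    # middle quintile reproduces the base table
    rr_norm = sample.rr_disease(quintile) / sample.rr_disease(3)
    inc_s = np.minimum(externals.incidence_smoker * rr_norm, 1.0)
    inc_f = np.minimum(externals.incidence_former * rr_norm, 1.0)

    u_s = sample.utility_by_age(ages, smoker=True, q=quintile)
    u_f = sample.utility_by_age(ages, smoker=False, q=quintile)
    if np.any(np.abs(u_s) > 1.0) or np.any(np.abs(u_f) > 1.0):
        # warn once per quintile per process; routine under sampled coefficients
        if quintile not in _utility_warned:
            _utility_warned.add(quintile)
            logger.warning(
                "utility outside [-1, 1] for quintile %d (values retained; "
                "further occurrences logged at DEBUG)", quintile
            )
        else:
            logger.debug("utility outside [-1, 1] for quintile %d", quintile)

    disutil = sample.disease_disutilities()
    costs = sample.disease_costs()
    return {
        "ages": ages,
        "m_s": m_s,
        "m_f": m_f,
        # fold the per-event disutility/cost into per-age per-person rates
        "qaly_s": u_s - inc_s @ disutil,
        "qaly_f": u_f - inc_f @ disutil,
        "cost_s": inc_s @ costs,
        "cost_f": inc_f @ costs,
        "inc_s": inc_s,
        "inc_f": inc_f,
    }


def _first_cycle_quit(
    sample: ParameterSample, quintile: int, arm: str, settings: ModelSettings
) -> float:
    base = sample.quit_rate(arm) if arm != "none" else settings.background_quit_rate
    return annual_quit_probability(
        base,
        sample.rr_quit(quintile),
        is_first_cycle=True,
        arm=arm if arm != "none" else "none",
        background_quit=settings.background_quit_rate,
    )


def run_cohort_trace(
    sample: ParameterSample,
    externals: ExternalInputs,
    quintile: int,
    arm: str,
    settings: ModelSettings,
    entry_age: int,
) -> CohortTrace:
    """Simulate one cohort (single entry age) cycle by cycle.

    Reference implementation: scalar loop over cycles, used directly for
    traces and as the oracle for the vectorised multi-age engine.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if not settings.entry_age_min <= entry_age <= settings.entry_age_max:
        raise ValueError(f"entry age {entry_age} outside the configured range")
    tab = _quintile_tables(sample, externals, quintile)
    q_first = _first_cycle_quit(sample, quintile, arm, settings)
    q_later = annual_quit_probability(
        0.0, sample.rr_quit(quintile), is_first_cycle=False, arm=arm,
        background_quit=settings.background_quit_rate,
    )
    r = settings.discount_rate
    n_cycles = settings.age_cap - entry_age

    S, F, D = 1.0, 0.0, 0.0
    rec = {k: [] for k in ("S", "F", "D", "ev", "qaly", "cost")}
    for t in range(n_cycles):
        a = entry_age + t - externals.ages[0]  # index into age tables
        disc = (1.0 + r) ** (-t)
        ev = S * tab["inc_s"][a] + F * tab["inc_f"][a]
        qaly = disc * (S * tab["qaly_s"][a] + F * tab["qaly_f"][a])
        cost = disc * (S * tab["cost_s"][a] + F * tab["cost_f"][a])
        if t == 0 and arm != "none":
            cost += sample.intervention_cost(arm)
        rec["S"].append(S)
        rec["F"].append(F)
        rec["D"].append(D)
        rec["ev"].append(ev)
        rec["qaly"].append(qaly)
        rec["cost"].append(cost)
        # transitions: quit, then die
        q = q_first if t == 0 else q_later
        S_q = S * (1.0 - q)
        F_q = F + S * q
        deaths = S_q * tab["m_s"][a] + F_q * tab["m_f"][a]
        S = S_q * (1.0 - tab["m_s"][a])
        F = F_q * (1.0 - tab["m_f"][a])
        D = D + deaths

    return CohortTrace(
        entry_age=entry_age,
        quintile=quintile,
        arm=arm,
        cycles=np.arange(n_cycles),
        smoker=np.array(rec["S"]),
        former=np.array(rec["F"]),
        dead=np.array(rec["D"]),
        events=np.array(rec["ev"]),
        disc_qaly=np.array(rec["qaly"]),
        disc_cost=np.array(rec["cost"]),
    )


def _per_smoker_all_ages(
    tab: dict,
    q_first: float,
    q_later: float,
    intervention_cost: float,
    settings: ModelSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-entry-age (QALY, cost) totals for one quintile x arm."""
    entry = settings.entry_ages
    n = entry.shape[0]
    offsets = entry - int(tab["ages"][0])   # index of each cohort's entry age
    r = settings.discount_rate
    max_cycles = settings.age_cap - int(entry.min())

    S = np.ones(n)
    F = np.zeros(n)
    qaly_tot = np.zeros(n)
    # intervention cost lands in cycle 0 (discount factor 1)
    cost_tot = np.full(n, intervention_cost, dtype=float)

    for t in range(max_cycles):
        alive = (entry + t) < settings.age_cap
        if not alive.any():
            break
        idx = np.minimum(offsets + t, tab["m_s"].shape[0] - 1)
        disc = (1.0 + r) ** (-t)
        qaly_tot += np.where(
            alive, disc * (S * tab["qaly_s"][idx] + F * tab["qaly_f"][idx]), 0.0
        )
        cost_tot += np.where(
            alive, disc * (S * tab["cost_s"][idx] + F * tab["cost_f"][idx]), 0.0
        )
        q = q_first if t == 0 else q_later
        S_q = S * (1.0 - q)
        F_q = F + S * q
        S = np.where(alive, S_q * (1.0 - tab["m_s"][idx]), S)
        F = np.where(alive, F_q * (1.0 - tab["m_f"][idx]), F)
    return qaly_tot, cost_tot


def per_smoker_lifetime_outcomes(
    sample: ParameterSample,
    externals: ExternalInputs,
    quintile: int,
    arm: str,
    settings: ModelSettings,
) -> tuple[float, float]:
    """Entry-age-distribution-weighted discounted (QALYs, costs) per smoker."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    w = settings.entry_weights
    tab = _quintile_tables(sample, externals, quintile)
    q_first = _first_cycle_quit(sample, quintile, arm, settings)
    q_later = annual_quit_probability(
        0.0, sample.rr_quit(quintile), is_first_cycle=False, arm=arm,
        background_quit=settings.background_quit_rate,
    )
    cost0 = sample.intervention_cost(arm) if arm != "none" else 0.0
    qaly, cost = _per_smoker_all_ages(tab, q_first, q_later, cost0, settings)
    return float(qaly @ w), float(cost @ w)


def _all_per_smoker_outcomes(
    sample: ParameterSample, externals: ExternalInputs, settings: ModelSettings
) -> dict:
    """(quintile, arm) -> per-smoker (QALY, cost); shares age tables per quintile."""
    out = {}
    for quintile in range(1, 6):
        tab = _quintile_tables(sample, externals, quintile)
        q_later = annual_quit_probability(
            0.0, sample.rr_quit(quintile), is_first_cycle=False,
            background_quit=settings.background_quit_rate,
        )
        w = settings.entry_weights
        for arm in ARMS:
            q_first = _first_cycle_quit(sample, quintile, arm, settings)
            cost0 = sample.intervention_cost(arm) if arm != "none" else 0.0
            qaly, cost = _per_smoker_all_ages(tab, q_first, q_later, cost0, settings)
            out[(quintile, arm)] = (float(qaly @ w), float(cost @ w))
    return out


def population_arm_outcomes(
    sample: ParameterSample,
    externals: ExternalInputs,
    population,
    arm: str,
    settings: ModelSettings,
    per_smoker: dict | None = None,
) -> ArmOutcome:
    """Scale per-smoker outcomes to the population of one arm.

    Smokers in quintile q number N w_q pi_q.  In an active arm only the
    uptaking fraction receives the intervention; non-uptakers follow the
    no-intervention pathway (and incur no intervention cost), so the
    quintile total is the uptake-weighted mix of the two pathways.
    """
    if per_smoker is None:
        per_smoker = _all_per_smoker_outcomes(sample, externals, settings)
    qalys = np.zeros(5)
    costs = np.zeros(5)
    per_smoker_out = {}
    sizes = population.quintile_sizes
    for quintile in range(1, 6):
        n_smokers = sizes[quintile - 1] * sample.prevalence(quintile)
        q_none, c_none = per_smoker[(quintile, "none")]
        if arm == "none":
            qalys[quintile - 1] = n_smokers * q_none
            costs[quintile - 1] = n_smokers * c_none
            per_smoker_out[quintile] = (q_none, c_none)
        else:
            u = sample.uptake(quintile)
            q_arm, c_arm = per_smoker[(quintile, arm)]
            qalys[quintile - 1] = n_smokers * (q_none + u * (q_arm - q_none))
            costs[quintile - 1] = n_smokers * (c_none + u * (c_arm - c_none))
            per_smoker_out[quintile] = (q_arm, c_arm)
    return ArmOutcome(arm=arm, qalys=qalys, costs=costs, per_smoker=per_smoker_out)
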