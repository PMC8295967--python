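"""Parameter book: the full set of uncertain model inputs and their sampling.

A :class:`ParameterBook` maps named quantities — per deprivation quintile
where applicable — to :class:`~dcea.distributions.DistributionSpec` objects,
alongside the fixed analysis settings (discount rate, background quit rate,
cost-effectiveness threshold, population size and quintile shares).  One
probabilistic-sensitivity-analysis iteration resolves the book into a
:class:`ParameterSample` of concrete values; the HRQoL regression
coefficients are drawn jointly through the Cholesky factor of their
covariance, everything else independently.

Naming scheme for scalar quantities (quintiles 1..5, IMD1 most deprived):

* ``prevalence_imd{q}`` — smoking prevalence
* ``rr_death_svn_{band}`` — relative risk of death, smokers v. nonsmokers,
  age bands 35_44 .. 75plus; ``rr_death_svf`` smokers v. former smokers
* ``rr_disease_imd{q}`` — relative risk of smoking-related disease (IMD5 = 1)
* ``quit_rate_{arm}`` — average 12-month quit rate of the intervention
* ``rr_quit_imd{q}`` — relative risk of quitting (IMD1 = 1)
* ``uptake_imd{q}`` — stop-smoking-service uptake
* ``cost_intervention_{arm}``, ``cost_{disease}``, ``disutility_{disease}``
* ``hrqol_{coef}`` — HRQoL regression coefficients (sample only; the book
  stores them as one multivariate-normal block under key ``hrqol``)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import DistributionSpec

logger = logging.getLogger(__name__)

QUINTILES = (1, 2, 3, 4, 5)
ARMS = ("none", "varenicline", "ecigarette")
ACTIVE_ARMS = ("varenicline", "ecigarette")
DISEASES = ("lung_cancer", "chd", "copd", "mi", "stroke", "asthma_exacerbation")

HRQOL_COEF_NAMES = (
    "constant",
    "age_25_34",
    "age_35_44",
    "age_45_54",
    "age_55_64",
    "age_65_74",
    "age_75plus",
    "smoker",
    "imd2",
    "imd3",
    "imd4",
    "imd5",
)

#: bounds applied to sampled values after transformation, by name prefix
_PROBABILITY_PREFIXES = ("prevalence_", "uptake_", "quit_rate_")
_POSITIVE_PREFIXES = ("rr_", "cost_", "disutility_")


@dataclass(frozen=True)
class BookSettings:
    """Fixed (not sampled) analysis settings."""

    discount_rate: float = 0.035
    background_quit_rate: float = 0.02
    threshold_k: float = 20000.0
    age_cap: int = 100
    entry_age_min: int = 18
    entry_age_max: int = 75

    def __post_init__(self):
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount rate must lie in [0, 1)")
        if not 18 <= self.entry_age_min <= self.entry_age_max <= 75:
            raise ValueError("entry ages must lie within [18, 75]")
        if self.age_cap <= self.entry_age_max:
            raise ValueError("age cap must exceed the oldest entry age")


@dataclass(frozen=True)
class PopulationSpec:
    """Region population: total size and quintile shares."""

    name: str
    size: float
    quintile_shares: tuple

    def __post_init__(self):
        shares = np.asarray(self.quintile_shares, dtype=float)
        if shares.shape != (5,):
            raise ValueError("quintile_shares must have five entries")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError(f"quintile shares sum to {shares.sum()}, not 1")
        if self.size <= 0:
            raise ValueError("population size must be positive")

    @property
    def quintile_sizes(self) -> np.ndarray:
        return self.size * np.asarray(self.quintile_shares, dtype=float)


#: scalar quantities every downstream consumer requires
REQUIRED_KEYS = tuple(
    [f"prevalence_imd{q}" for q in QUINTILES]
    + [f"rr_death_svn_{b}" for b in ("35_44", "45_54", "55_64", "65_74", "75plus")]
    + ["rr_death_svf"]
    + [f"rr_disease_imd{q}" for q in QUINTILES]
    + [f"quit_rate_{a}" for a in ACTIVE_ARMS]
    + [f"rr_quit_imd{q}" for q in QUINTILES]
    + [f"uptake_imd{q}" for q in QUINTILES]
    + [f"cost_intervention_{a}" for a in ACTIVE_ARMS]
    + [f"cost_{d}" for d in DISEASES]
    + [f"disutility_{d}" for d in DISEASES]
)


@dataclass
class ParameterBook:
    """All uncertain model inputs plus fixed settings for one region."""

    settings: BookSettings
    population: PopulationSpec
    entries: dict = field(default_factory=dict)  # name -> DistributionSpec
    hrqol: DistributionSpec | None = None        # mvnormal block
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [k for k in REQUIRED_KEYS if k not in self.entries]
        if missing:
            raise ValueError(f"parameter book is missing required entries: {missing}")
        if self.hrqol is None or self.hrqol.family != "mvnormal":
            raise ValueError("parameter book requires an mvnormal 'hrqol' block")
        names = tuple(self.hrqol.params.get("names", ()))
        if names != HRQOL_COEF_NAMES:
            raise ValueError("hrqol block must carry the standard coefficient names")
        # reference quintiles are fixed, never sampled
        for key in ("rr_quit_imd1", "rr_disease_imd5"):
            if self.entries[key].family != "fixed":
                raise ValueError(f"{key} is a reference category and must be fixed")

    def sampled_names(self) -> list[str]:
        """Names of genuinely sampled scalars (fixed entries excluded), sorted."""
        names = [k for k in sorted(self.entries) if self.entries[k].family != "fixed"]
        names += [f"hrqol_{c}" for c in HRQOL_COEF_NAMES]
        return names


class ParameterSample:
    """One concrete joint draw of every model input.

    Behaves as a read-only mapping from quantity name to value, with typed
    accessors for the quantities the cohort model consumes.
    """

    def __init__(self, values: dict):
        self._values = dict(values)

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __contains__(self, key: str) -> bool:
        return key in self._values

    def keys(self):
        return self._values.keys()

    def as_series(self) -> pd.Series:
        return pd.Series(self._values, dtype=float)

    def replace(self, **overrides) -> "ParameterSample":
        """Copy of the sample with some quantities overridden (what-if runs)."""
        unknown = set(overrides) - set(self._values)
        if unknown:
            raise KeyError(f"unknown quantities: {sorted(unknown)}")
        out = ParameterSample({**self._values, **overrides})
        out.truncation_count = getattr(self, "truncation_count", 0)
        return out

    # -- typed accessors ---------------------------------------------------

    def prevalence(self, q: int) -> float:
        return self._values[f"prevalence_imd{q}"]

    def uptake(self, q: int) -> float:
        return self._values[f"uptake_imd{q}"]

    def rr_quit(self, q: int) -> float:
        return self._values[f"rr_quit_imd{q}"]

    def rr_disease(self, q: int) -> float:
        return self._values[f"rr_disease_imd{q}"]

    def quit_rate(self, arm: str) -> float:
        return self._values[f"quit_rate_{arm}"]

    def intervention_cost(self, arm: str) -> float:
        return self._values[f"cost_intervention_{arm}"]

    def disease_costs(self) -> np.ndarray:
        return np.array([self._values[f"cost_{d}"] for d in DISEASES])

    def disease_disutilities(self) -> np.ndarray:
        return np.array([self._values[f"disutility_{d}"] for d in DISEASES])

    @property
    def rr_death_svf(self) -> float:
        return self._values["rr_death_svf"]

    def rr_death_svn_by_age(self, ages: np.ndarray) -> np.ndarray:
        """Smoker-v-nonsmoker mortality RR per age (1.0 below age 35)."""
        out = np.ones_like(np.asarray(ages, dtype=float))
        bands = [
            (35, 45, "rr_death_svn_35_44"),
            (45, 55, "rr_death_svn_45_54"),
            (55, 65, "rr_death_svn_55_64"),
            (65, 75, "rr_death_svn_65_74"),
            (75, 1000, "rr_death_svn_75plus"),
        ]
        for lo, hi, key in bands:
            mask = (ages >= lo) & (ages < hi)
            out[mask] = self._values[key]
        return out

    def hrqol_coefficient(self, name: str) -> float:
        return self._values[f"hrqol_{name}"]

    def utility_by_age(self, ages: np.ndarray, smoker: bool, q: int) -> np.ndarray:
        """HRQoL utility per age for a smoking status and quintile."""
        v = self._values
        u = np.full(np.asarray(ages).shape, v["hrqol_constant"], dtype=float)
        bands = [
            (25, 35, "age_25_34"),
            (35, 45, "age_35_44"),
            (45, 55, "age_45_54"),
            (55, 65, "age_55_64"),
            (65, 75, "age_65_74"),
            (75, 1000, "age_75plus"),
        ]
        for lo, hi, coef in bands:
            mask = (ages >= lo) & (ages < hi)
            u[mask] += v[f"hrqol_{coef}"]
        if smoker:
            u += v["hrqol_smoker"]
        if q != 1:  # IMD1 is the reference category
            u += v[f"hrqol_imd{q}"]
        return u


def draw_sample(book: ParameterBook, rng: np.random.Generator) -> ParameterSample:
    """Draw one joint :class:`ParameterSample` from the book.

    Scalars are drawn independently in sorted-name order (so results are
    reproducible for a given seeded generator regardless of insertion order);
    the HRQoL coefficient vector is drawn jointly via the Cholesky factor of
    its covariance.  Probabilities are truncated to [0, 1] and relative
    risks/costs to (0, inf); truncations are counted on the sample as
    ``sample.truncation_count``.
    """
    book.validate()
    values: dict = {}
    truncations = 0
    for name in sorted(book.entries):
        spec = book.entries[name]
        x = spec.sample(rng)
        if name.startswith(_PROBABILITY_PREFIXES):
            clipped = min(max(x, 0.0), 1.0)
        elif name.startswith(_POSITIVE_PREFIXES):
            clipped = max(x, 1e-12)
        else:
            clipped = x
        if clipped != x:
            truncations += 1
            logger.warning("sampled %s=%.6g truncated to %.6g", name, x, clipped)
        values[name] = float(clipped)

    coefs = np.atleast_1d(book.hrqol.sample(rng))
    for cname, cval in zip(HRQOL_COEF_NAMES, coefs):
        values[f"hrqol_{cname}"] = float(cval)

    sample = ParameterSample(values)
    sample.truncation_count = truncations
    return sample


def sample_at_means(book: ParameterBook) -> ParameterSample:
    """Deterministic base-case sample with every quantity at its mean."""
    book.validate()
    values = {name: float(np.asarray(spec.mean)) for name, spec in book.entries.items()}
    for cname, cval in zip(HRQOL_COEF_NAMES, np.atleast_1d(book.hrqol.mean)):
        values[f"hrqol_{cname}"] = float(cval)
    sample = ParameterSample(values)
    sample.truncation_count = 0
    return sample


def samples_to_frame(samples: list[ParameterSample], names: list[str]) -> pd.DataFrame:
    """Stack samples into the iteration x input matrix consumed by VOI/ANCOVA."""
    return pd.DataFrame([[s[n] for n in names] for s in samples], columns=names)
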