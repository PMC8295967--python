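"""Parametric distributions for uncertain model inputs.

Every uncertain quantity in the decision model is described by a
:class:`DistributionSpec`: a distribution family (beta, gamma, lognormal,
multivariate normal, or a degenerate "fixed" value) together with its
family-specific parameters.  Probabilities (smoking prevalence, quit rates,
service uptake) use beta distributions; strictly positive costs and
disutilities use gammas; relative risks use lognormals parameterised by the
mean (``lm``) and standard deviation (``lv``) of the log-transformed value;
the health-related quality of life (HRQoL) regression coefficients are drawn
jointly from a multivariate normal.

The moment-matching constructors reproduce the standard health-economics
recipes: a beta matched to a proportion's mean and standard error, and a
gamma matched to a positive quantity's mean and standard error (typically
"standard error equal to 10% of the mean" when no variance estimate is
published).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "DistributionSummary",
    "InfeasibleVarianceError",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "distribution_summary",
]

FAMILIES = ("beta", "gamma", "lognormal", "mvnormal", "fixed")


class InfeasibleVarianceError(ValueError):
    """Requested variance cannot be realised by the target family."""


def _as_cov(cov) -> np.ndarray:
    c = np.asarray(cov, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    # PSD check with a small tolerance for rounding in stored fixtures
    eig = np.linalg.eigvalsh(c)
    if eig.min() < -1e-10 * max(1.0, eig.max()):
        raise ValueError("covariance must be positive semi-definite")
    return c


@dataclass(frozen=True)
class DistributionSpec:
    """A sampled model input: family plus family-specific parameters.

    params by family:
      beta:      {"alpha": a>0, "beta": b>0}
      gamma:     {"shape": k>0, "scale": s>0}
      lognormal: {"lm": mean of log value, "lv": sd of log value > 0}
      mvnormal:  {"mean": vector, "cov": PSD matrix, "names": component names}
      fixed:     {"value": v}
    """

    family: str
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = self.params
        if self.family == "beta":
            if not (p["alpha"] > 0 and p["beta"] > 0):
                raise ValueError("beta requires alpha > 0 and beta > 0")
        elif self.family == "gamma":
            if not (p["shape"] > 0 and p["scale"] > 0):
                raise ValueError("gamma requires shape > 0 and scale > 0")
        elif self.family == "lognormal":
            if not p["lv"] > 0:
                raise ValueError("lognormal requires lv > 0")
        elif self.family == "mvnormal":
            mean = np.asarray(p["mean"], dtype=float)
            cov = _as_cov(p["cov"])
            if mean.shape[0] != cov.shape[0]:
                raise ValueError("mvnormal mean/cov dimension mismatch")
        elif self.family == "fixed":
            float(p["value"])

    # -- analytic moments -------------------------------------------------

    @property
    def mean(self):
        p = self.params
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "lognormal":
            return float(np.exp(p["lm"] + p["lv"] ** 2 / 2.0))
        if self.family == "mvnormal":
            return np.asarray(p["mean"], dtype=float)
        return float(p["value"])

    @property
    def sd(self):
        p = self.params
        if self.family == "beta":
            a, b = p["alpha"], p["beta"]
            return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))
        if self.family == "gamma":
            return float(np.sqrt(p["shape"]) * p["scale"])
        if self.family == "lognormal":
            lm, lv = p["lm"], p["lv"]
            return float(np.sqrt((np.exp(lv**2) - 1.0) * np.exp(2 * lm + lv**2)))
        if self.family == "mvnormal":
            return np.sqrt(np.diag(np.asarray(p["cov"], dtype=float)))
        return 0.0

    @property
    def median(self):
        if self.family == "lognormal":
            return float(np.exp(self.params["lm"]))
        return self.quantile(0.5)

    def frozen(self):
        """scipy frozen distribution for the scalar families."""
        p = self.params
        if self.family == "beta":
            return stats.beta(p["alpha"], p["beta"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["lv"], scale=np.exp(p["lm"]))
        raise ValueError(f"no scipy frozen distribution for family {self.family!r}")

    def quantile(self, q):
        if self.family == "fixed":
            return np.full_like(np.asarray(q, dtype=float), self.params["value"]) + 0.0
        if self.family == "mvnormal":
            mean = np.asarray(self.params["mean"], dtype=float)
            sd = self.sd
            return mean + stats.norm.ppf(q) * sd  # componentwise
        return self.frozen().ppf(q)

    # -- sampling ----------------------------------------------------------

    def sample(self, rng: np.random.Generator):
        p = self.params
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"])
        if self.family == "gamma":
            return rng.gamma(p["shape"]) * p["scale"]
        if self.family == "lognormal":
            return float(np.exp(p["lm"] + p["lv"] * rng.standard_normal()))
        if self.family == "mvnormal":
            mean = np.asarray(p["mean"], dtype=float)
            cov = np.asarray(p["cov"], dtype=float)
            z = rng.standard_normal(mean.shape[0])
            if not cov.any():  # degenerate block (flattened coefficients)
                return mean.copy()
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                try:  # semidefinite blocks (e.g. zeroed coefficients)
                    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
                except np.linalg.LinAlgError as exc:
                    names = p.get("names")
                    raise np.linalg.LinAlgError(
                        f"Cholesky decomposition failed for mvnormal block "
                        f"{names if names is not None else ''}"
                    ) from exc
            return mean + chol @ z
        return float(p["value"])

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        p = dict(self.params)
        if self.family == "mvnormal":
            p["mean"] = np.asarray(p["mean"], dtype=float).tolist()
            p["cov"] = np.asarray(p["cov"], dtype=float).tolist()
            if "names" in p:
                p["names"] = list(p["names"])
        return {"family": self.family, "params": p}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return cls(family=d["family"], params=dict(d["params"]))

    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls("fixed", {"value": float(value)})


@dataclass(frozen=True)
class DistributionSummary:
    mean: float
    sd: float
    quantile: Callable


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Moment-match a Beta(alpha, beta) to a proportion's mean and standard error.

    nu = mean (1-mean) / se^2 - 1;  alpha = mean nu;  beta = (1-mean) nu.

    Raises :class:`InfeasibleVarianceError` when se^2 >= mean (1-mean), the
    maximum variance any beta with that mean can attain.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie strictly in (0, 1), got {mean}")
    if se <= 0.0:
        raise ValueError(f"se must be positive, got {se}")
    if se**2 >= mean * (1.0 - mean):
        raise InfeasibleVarianceError(
            f"se^2 = {se**2:.3g} >= mean(1-mean) = {mean * (1 - mean):.3g}; "
            "no beta distribution has this mean and variance"
        )
    nu = mean * (1.0 - mean) / se**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Moment-match a Gamma(shape, scale) to a positive mean and standard error.

    shape = (mean/se)^2, scale = se^2/mean; both moments are reproduced
    exactly.  The shape depends only on the ratio se/mean, so the common
    "se = 10% of mean" convention always yields shape 100.
    """
    if mean <= 0.0 or se <= 0.0:
        raise ValueError(f"mean and se must be positive, got mean={mean}, se={se}")
    return (mean / se) ** 2, se**2 / mean


def distribution_summary(spec: DistributionSpec) -> DistributionSummary:
    """Analytic mean, sd and quantile function of a spec (Table-of-parameters view)."""
    return DistributionSummary(mean=spec.mean, sd=spec.sd, quantile=spec.quantile)
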