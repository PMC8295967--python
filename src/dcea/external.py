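"""Synthetic stand-ins for external model inputs that are not publicly printed.

The cohort model needs several tables the analysis takes from national
statistics and prior literature: all-cause mortality by age and deprivation
quintile, smoking-status proportions, smoking-related disease incidence by
age and smoking status, baseline quality-adjusted life expectancy (QALE) per
quintile, the quintile shares of health opportunity costs and the Atkinson
inequality-aversion parameter.  None of these are deposited with the source
publication, so this module generates deterministic synthetic versions from
the presets in ``data/scenarios.yaml``.

Every table is SYNTHETIC: plausible in shape (Gompertz-like mortality,
deprivation gradients in the conventional direction) but not estimates of the
real English quantities.  The ``flat`` scenario removes every quintile
gradient and is the basis of the pipeline's symmetry tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .parameters import DISEASES, QUINTILES

__all__ = ["ExternalInputs", "generate_external_inputs", "available_scenarios"]

AGE_MIN, AGE_MAX = 18, 100


def _load_scenarios() -> dict:
    with importlib.resources.files("dcea.data").joinpath("scenarios.yaml").open() as fh:
        return yaml.safe_load(fh)


def available_scenarios() -> list[str]:
    return sorted(_load_scenarios())


@dataclass
class ExternalInputs:
    """Age x quintile external tables plus equity settings (synthetic)."""

    ages: np.ndarray                     # (A,) 18..100
    all_cause_mortality: np.ndarray      # (A, 5) annual probabilities
    p_smoker: np.ndarray                 # (A, 5) smoking-status proportions
    p_former: np.ndarray                 # (A, 5)
    p_non: np.ndarray                    # (A, 5)
    incidence_smoker: np.ndarray         # (A, 6) annual event probabilities
    incidence_former: np.ndarray         # (A, 6)
    baseline_qale: np.ndarray            # (5,) QALYs per person
    opportunity_cost_shares: np.ndarray  # (5,) sum to 1
    inequality_aversion: float           # Atkinson epsilon
    scenario: str = "default"
    seed: int = 0
    provenance: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        A = self.ages.shape[0]
        for name in ("all_cause_mortality", "p_smoker", "p_former", "p_non"):
            arr = getattr(self, name)
            if arr.shape != (A, 5):
                raise ValueError(f"{name} must have shape ({A}, 5)")
        if np.any(self.all_cause_mortality < 0) or np.any(self.all_cause_mortality >= 1):
            raise ValueError("mortality rates must lie in [0, 1)")
        if np.any(np.diff(self.all_cause_mortality, axis=0) < -1e-12):
            raise ValueError("mortality must be non-decreasing in age")
        props = self.p_smoker + self.p_former + self.p_non
        if not np.allclose(props, 1.0, atol=1e-9):
            raise ValueError("smoking-status proportions must sum to 1")
        if abs(self.opportunity_cost_shares.sum() - 1.0) > 1e-9:
            raise ValueError("opportunity-cost shares must sum to 1")
        if np.any(np.diff(self.opportunity_cost_shares) > 1e-12):
            raise ValueError("opportunity-cost shares must not increase from IMD1 to IMD5")
        if np.any(np.diff(self.baseline_qale) < -1e-12):
            raise ValueError("baseline QALE must not decrease from IMD1 to IMD5")
        if np.any(self.baseline_qale <= 0):
            raise ValueError("baseline QALE must be positive")
        if self.inequality_aversion < 0:
            raise ValueError("inequality aversion must be non-negative")

    # -- tidy exports ------------------------------------------------------

    def mortality_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.all_cause_mortality,
            index=pd.Index(self.ages, name="age"),
            columns=[f"imd{q}" for q in QUINTILES],
        )

    def incidence_frame(self) -> pd.DataFrame:
        rows = []
        for status, table in (("smoker", self.incidence_smoker), ("former", self.incidence_former)):
            df = pd.DataFrame(table, index=pd.Index(self.ages, name="age"), columns=list(DISEASES))
            df.insert(0, "status", status)
            rows.append(df.reset_index())
        return pd.concat(rows, ignore_index=True)


def generate_external_inputs(seed: int = 0, scenario: str = "default") -> ExternalInputs:
    """Build the synthetic external tables for one scenario, deterministically.

    The seed perturbs only scale factors (overall mortality level, per-disease
    incidence level) through a lognormal jitter, so age monotonicity and
    quintile orderings hold by construction for every seed.  ``flat`` sets the
    jitter to zero and removes all quintile gradients.
    """
    presets = _load_scenarios()
    if scenario not in presets:
        raise ValueError(f"unknown scenario {scenario!r}; available: {sorted(presets)}")
    cfg = presets[scenario]
    rng = np.random.default_rng(seed)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    A = ages.shape[0]
    years = (ages - AGE_MIN).astype(float)

    jitter_sd = float(cfg.get("jitter_sd", 0.0))

    def jitter() -> float:
        # one draw per call even when sd == 0, to keep the stream layout stable
        z = rng.standard_normal()
        return float(np.exp(jitter_sd * z))

    mort = cfg["mortality"]
    base_curve = mort["base_rate"] * np.exp(mort["slope"] * years) * jitter()
    mult = np.asarray(mort["quintile_multipliers"], dtype=float)
    all_cause = np.minimum(base_curve[:, None] * mult[None, :], mort["cap"])

    sp = cfg["smoking_proportions"]
    smoker0 = np.asarray(sp["smoker_at_18"], dtype=float)
    p_smoker = np.maximum(
        smoker0[None, :] - sp["smoker_age_decline"] * years[:, None], sp["smoker_floor"]
    )
    p_former = np.minimum(sp["former_at_18"] + sp["former_age_rise"] * years, sp["former_cap"])
    p_former = np.broadcast_to(p_former[:, None], (A, 5)).copy()
    p_non = 1.0 - p_smoker - p_former

    inc = cfg["disease_incidence"]
    inc_smoker = np.empty((A, len(DISEASES)))
    for j, d in enumerate(DISEASES):
        inc_smoker[:, j] = inc[d]["base"] * np.exp(inc[d]["slope"] * years) * jitter()
    inc_smoker = np.minimum(inc_smoker, inc["cap"])
    former_rel = np.full(len(DISEASES), inc["former_relative_rate"])
    former_rel[DISEASES.index("asthma_exacerbation")] = inc["former_relative_rate_asthma"]
    inc_former = inc_smoker * former_rel[None, :]

    ext = ExternalInputs(
        ages=ages,
        all_cause_mortality=all_cause,
        p_smoker=p_smoker,
        p_former=p_former,
        p_non=p_non,
        incidence_smoker=inc_smoker,
        incidence_former=inc_former,
        baseline_qale=np.asarray(cfg["baseline_qale"], dtype=float),
        opportunity_cost_shares=np.asarray(cfg["opportunity_cost_shares"], dtype=float),
        inequality_aversion=float(cfg["inequality_aversion"]),
        scenario=scenario,
        seed=seed,
        metadata={"jitter_sd": jitter_sd},
    )
    ext.validate()
    return ext
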