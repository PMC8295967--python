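"""Packaged parameter-book fixtures and book file I/O.

``fixture_parameter_book`` returns the national (England) book with the
published distribution parameters verbatim, or a local-authority book (York,
Sheffield) whose smoking prevalence comes from the published local means and
95% confidence intervals — converted to betas by moment matching — with every
other uncertain input inherited from the national book.

The HRQoL coefficient covariance is not published; it is rebuilt here as
``D R D`` with standard errors ``D = max(0.10 |coef|, floor)`` and an
exchangeable correlation ``R`` (off-diagonal ``rho``), a synthetic
stand-in that preserves the correlated-draw mechanism (Cholesky factor of a
positive-definite covariance).
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import yaml

from .distributions import DistributionSpec, beta_from_mean_se
from .parameters import (
    HRQOL_COEF_NAMES,
    QUINTILES,
    BookSettings,
    ParameterBook,
    PopulationSpec,
)

__all__ = [
    "REGIONS",
    "fixture_parameter_book",
    "build_hrqol_covariance",
    "flatten_book",
    "book_to_dict",
    "book_from_dict",
    "save_book",
    "load_book",
]

REGIONS = ("england", "york", "sheffield")


def _load_yaml(name: str) -> dict:
    with importlib.resources.files("dcea.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def build_hrqol_covariance(
    coefficients: dict,
    se_fraction: float = 0.10,
    se_floor: float = 0.005,
    rho: float = 0.2,
) -> DistributionSpec:
    """Multivariate-normal HRQoL block with a synthetic exchangeable covariance."""
    names = tuple(coefficients)
    means = np.array([coefficients[n] for n in names], dtype=float)
    d = np.maximum(se_fraction * np.abs(means), se_floor)
    k = means.shape[0]
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    cov = np.outer(d, d) * corr
    return DistributionSpec("mvnormal", {"mean": means, "cov": cov, "names": names})


def _england_book() -> ParameterBook:
    raw = _load_yaml("england.yaml")
    settings = BookSettings(**raw["settings"])
    population = PopulationSpec(
        name="england",
        size=raw["population_size"],
        quintile_shares=tuple(raw["quintile_shares"]),
    )
    entries = {
        name: DistributionSpec(e["family"], dict(e["params"]))
        for name, e in raw["entries"].items()
    }

    cad = raw["costs_and_disutilities"]
    sf = cad["se_fraction"]

    def gamma_spec(mean: float) -> DistributionSpec:
        from .distributions import gamma_from_mean_se

        shape, scale = gamma_from_mean_se(mean, sf * mean)
        return DistributionSpec("gamma", {"shape": shape, "scale": scale})

    for arm, mean in cad["intervention_costs"].items():
        entries[f"cost_intervention_{arm}"] = gamma_spec(mean)
    for d, mean in cad["disease_costs"].items():
        entries[f"cost_{d}"] = gamma_spec(mean)
    for d, mean in cad["disease_disutilities"].items():
        entries[f"disutility_{d}"] = gamma_spec(mean)

    hb = raw["hrqol"]
    coefficients = {n: hb["coefficients"][n] for n in HRQOL_COEF_NAMES}
    hrqol = build_hrqol_covariance(
        coefficients, hb["se_fraction"], hb["se_floor"], hb["rho"]
    )
    book = ParameterBook(
        settings=settings,
        population=population,
        entries=entries,
        hrqol=hrqol,
        metadata={"region": "england", "provenance": raw.get("provenance", {})},
    )
    book.validate()
    return book


def fixture_parameter_book(region: str = "england") -> ParameterBook:
    """The packaged parameter book for ``england``, ``york`` or ``sheffield``."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; available: {REGIONS}")
    book = _england_book()
    if region == "england":
        return book

    raw = _load_yaml(f"{region}.yaml")
    book.population = PopulationSpec(
        name=region,
        size=raw["population_size"],
        quintile_shares=tuple(raw["quintile_shares"]),
    )
    for q in QUINTILES:
        row = raw["prevalence"][f"imd{q}"]
        mean = row["mean"] / 100.0
        lo, hi = (v / 100.0 for v in row["ci"])
        se = (hi - lo) / (2.0 * 1.959963984540054)  # normal-approximation CI
        alpha, beta = beta_from_mean_se(mean, se)
        book.entries[f"prevalence_imd{q}"] = DistributionSpec(
            "beta", {"alpha": alpha, "beta": beta}
        )
    book.metadata = {
        "region": region,
        "provenance": raw.get("provenance", {}),
        "notes": "quintile shares are synthetic presets; prevalence from published local means/CIs",
    }
    book.validate()
    return book


def flatten_book(book: ParameterBook) -> ParameterBook:
    """Remove every quintile gradient from a book (symmetry/flat scenario).

    Quintile-specific quantities are fixed at a common value (the IMD-wide
    mean of the published means for prevalence and uptake; 1 for relative
    risks) and the HRQoL IMD coefficients are pinned to zero, so per-smoker
    outcomes are identical across quintiles draw by draw.  Non-quintile
    quantities keep their original distributions.
    """
    flat = ParameterBook(
        settings=book.settings,
        population=PopulationSpec(
            name=book.population.name + "-flat",
            size=book.population.size,
            quintile_shares=(0.2, 0.2, 0.2, 0.2, 0.2),
        ),
        entries=dict(book.entries),
        hrqol=book.hrqol,
        metadata={**book.metadata, "flattened": True},
    )
    prev_mean = float(np.mean([book.entries[f"prevalence_imd{q}"].mean for q in QUINTILES]))
    upt_mean = float(np.mean([book.entries[f"uptake_imd{q}"].mean for q in QUINTILES]))
    for q in QUINTILES:
        flat.entries[f"prevalence_imd{q}"] = DistributionSpec.fixed(prev_mean)
        flat.entries[f"uptake_imd{q}"] = DistributionSpec.fixed(upt_mean)
        flat.entries[f"rr_disease_imd{q}"] = DistributionSpec.fixed(1.0)
        flat.entries[f"rr_quit_imd{q}"] = DistributionSpec.fixed(1.0)

    names = tuple(book.hrqol.params["names"])
    mean = np.array(book.hrqol.params["mean"], dtype=float).copy()
    cov = np.array(book.hrqol.params["cov"], dtype=float).copy()
    for i, n in enumerate(names):
        if n.startswith("imd"):
            mean[i] = 0.0
            cov[i, :] = 0.0
            cov[:, i] = 0.0
    flat.hrqol = DistributionSpec("mvnormal", {"mean": mean, "cov": cov, "names": names})
    flat.validate()
    return flat


# -- book file round-trip --------------------------------------------------


def book_to_dict(book: ParameterBook) -> dict:
    return {
        "region": book.population.name,
        "population_size": float(book.population.size),
        "quintile_shares": list(book.population.quintile_shares),
        "settings": {
            "discount_rate": book.settings.discount_rate,
            "background_quit_rate": book.settings.background_quit_rate,
            "threshold_k": book.settings.threshold_k,
            "age_cap": book.settings.age_cap,
            "entry_age_min": book.settings.entry_age_min,
            "entry_age_max": book.settings.entry_age_max,
        },
        "entries": {name: spec.to_dict() for name, spec in book.entries.items()},
        "hrqol": book.hrqol.to_dict(),
        "metadata": dict(book.metadata),
    }


def book_from_dict(d: dict) -> ParameterBook:
    book = ParameterBook(
        settings=BookSettings(**d["settings"]),
        population=PopulationSpec(
            name=d["region"],
            size=d["population_size"],
            quintile_shares=tuple(d["quintile_shares"]),
        ),
        entries={n: DistributionSpec.from_dict(e) for n, e in d["entries"].items()},
        hrqol=DistributionSpec.from_dict(d["hrqol"]),
        metadata=dict(d.get("metadata", {})),
    )
    book.validate()
    return book


def save_book(book: ParameterBook, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(book_to_dict(book), fh, sort_keys=True)


def load_book(path) -> ParameterBook:
    with open(path) as fh:
        return book_from_dict(yaml.safe_load(fh))
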