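"""Orchestration: one call from parameter book to the full report bundle.

``run_full_pipeline`` executes the whole workflow — PSA, equity summary
table, value of information, ANCOVA — and writes a bundle of CSVs plus a
JSON manifest recording seeds, scenario, truncation counts and file hashes,
enough to reproduce the bundle exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ancova import ancova_report
from .external import available_scenarios, generate_external_inputs
from .fixtures import REGIONS, fixture_parameter_book, flatten_book, load_book
from .psa import COMPARISONS, base_case, psa_summary_table, run_psa, scatter_frame
from .voi import voi_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_run_config", "run_full_pipeline"]

_KNOWN_KEYS = {
    "region",
    "book_path",
    "scenario",
    "externals_seed",
    "n_iterations",
    "seed",
    "epsilon",
    "comparisons",
    "output_dir",
    "reports",
    "voi_comparison",
}
_KNOWN_REPORTS = {"psa", "voi", "ancova"}


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration."""

    region: str = "england"
    book_path: str | None = None
    scenario: str = "default"
    externals_seed: int = 0
    n_iterations: int = 1000
    seed: int = 42
    epsilon: float | None = None
    comparisons: tuple = tuple(c[0] for c in COMPARISONS)
    output_dir: str = "dcea-output"
    reports: tuple = ("psa", "voi", "ancova")
    voi_comparison: str = "varenicline_vs_ecigarette"

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.book_path is None and self.region not in REGIONS and self.region != "flat":
            raise ValueError(f"unknown region {self.region!r}")
        if self.scenario not in available_scenarios():
            raise ValueError(f"unknown scenario {self.scenario!r}")
        unknown = set(self.reports) - _KNOWN_REPORTS
        if unknown:
            raise ValueError(f"unknown reports {unknown}")
        known_comp = {c[0] for c in COMPARISONS}
        unknown = set(self.comparisons) - known_comp
        if unknown:
            raise ValueError(f"unknown comparisons {unknown}")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "comparisons" in raw:
        raw["comparisons"] = tuple(raw["comparisons"])
    if "reports" in raw:
        raw["reports"] = tuple(raw["reports"])
    return RunConfig(**raw)


def _resolve_book(config: RunConfig):
    if config.book_path is not None:
        return load_book(config.book_path)
    if config.region == "flat" or config.scenario == "flat":
        return flatten_book(fixture_parameter_book("england" if config.region == "flat" else config.region))
    return fixture_parameter_book(config.region)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute PSA -> equity summaries -> VOI -> ANCOVA and write the bundle.

    Returns the manifest dictionary.  On a stage failure, partial outputs are
    retained and the manifest notes the failed stage before the exception is
    re-raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "dcea_version": __version__,
        "config": {**asdict(config), "comparisons": list(config.comparisons), "reports": list(config.reports)},
        "stages": {},
        "files": {},
    }
    book = _resolve_book(config)
    externals = generate_external_inputs(config.externals_seed, config.scenario)
    comparisons = [c for c in COMPARISONS if c[0] in config.comparisons]

    def write(df: pd.DataFrame, name: str, index: bool) -> None:
        path = out / name
        df.to_csv(path, index=index)
        manifest["files"][name] = _sha256(path)

    try:
        stage = "psa"
        psa = run_psa(
            book,
            externals,
            comparisons=comparisons,
            n=config.n_iterations,
            seed=config.seed,
            epsilon=config.epsilon,
        )
        manifest["stages"]["psa"] = {
            "n_iterations": psa.n_iterations,
            "seed": psa.seed,
            "truncation_count": psa.truncation_count,
            **psa.metadata,
        }
        if "psa" in config.reports:
            write(psa.inputs, "inputs.csv", index=False)
            write(psa.outputs, "outputs.csv", index=False)
            summary = psa_summary_table(psa)
            bc = base_case(book, externals, comparisons=comparisons, epsilon=config.epsilon)
            summary.insert(0, "base_case_inhb", bc["inhb"])
            summary.insert(1, "base_case_delta", bc["delta"])
            write(summary, "summary.csv", index=True)
            write(scatter_frame(psa), "scatter.csv", index=False)

        if "voi" in config.reports:
            stage = "voi"
            voi = voi_report(
                psa,
                comparison=config.voi_comparison,
                threshold_k=book.settings.threshold_k,
                seed=config.seed,
            )
            write(voi, "voi.csv", index=False)

        if "ancova" in config.reports:
            stage = "ancova"
            write(ancova_report(psa), "ancova.csv", index=False)
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.error("pipeline stage %r failed; partial outputs retained in %s", stage, out)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
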