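"""ANCOVA-style variance decomposition of PSA outputs.

A single main-effects linear model of a PSA output on all (standardised)
sampled inputs attributes the output's variation to named parameter groups
by sums of squares.  Because PSA inputs are sampled independently, the
design is near-orthogonal and the attribution is essentially unique; the
default is the marginal (drop-one-group, type-III-like) attribution, with a
sequential (type-I) mode for comparison.  Shares are reported as fractions
of the output's total sum of squares; the residual share is 1 - R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["AncovaReport", "ancova_decompose", "ancova_report"]


@dataclass
class AncovaReport:
    """Per-group explained-variance shares for one output."""

    shares: pd.Series     # group -> fraction of total SS
    r_squared: float
    residual: float
    ss_type: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not ((self.shares >= -1e-9) & (self.shares <= 1.0 + 1e-9)).all():
            raise ValueError("shares must lie in [0, 1]")
        # with independently sampled inputs the sum stays near 1; chance
        # sample correlation can push marginal attributions slightly past it
        if self.shares.sum() > 1.25:
            raise ValueError("group shares sum far beyond 1; inputs are collinear")
        if self.shares.sum() > 1.0 + 0.02:
            logger.warning(
                "group shares sum to %.4f (> 1.02): inputs are not orthogonal "
                "in this sample", float(self.shares.sum()),
            )


def _explained_ss(y: np.ndarray, X: np.ndarray) -> float:
    """Explained sum of squares of an OLS fit with intercept."""
    if X.shape[1] == 0:
        return 0.0
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(((model.fittedvalues - y.mean()) ** 2).sum())


def ancova_decompose(
    outputs: np.ndarray,
    inputs: pd.DataFrame,
    groups: dict,
    ss_type: str = "marginal",
) -> AncovaReport:
    """Attribute an output's variance to parameter groups.

    ``groups`` maps a group name to a list of input columns; groups must be
    disjoint.  ``ss_type='marginal'`` uses drop-one-group delta-SS against
    the full model; ``'sequential'`` adds groups in the given order.
    A constant output yields all-zero shares and R^2 = 0 with a warning.
    """
    y = np.asarray(outputs, dtype=float)
    if ss_type not in ("marginal", "sequential"):
        raise ValueError("ss_type must be 'marginal' or 'sequential'")
    all_cols: list[str] = []
    for name, cols in groups.items():
        if not cols:
            raise ValueError(f"group {name!r} is empty")
        overlap = set(cols) & set(all_cols)
        if overlap:
            raise ValueError(f"groups must be disjoint; {overlap} repeated")
        all_cols.extend(cols)
    missing = [c for c in all_cols if c not in inputs.columns]
    if missing:
        raise ValueError(f"group columns absent from inputs: {missing}")
    if len(y) != len(inputs):
        raise ValueError("outputs and inputs must have aligned iterations")
    if len(y) <= len(all_cols) + 10:
        raise ValueError("need n > number of columns + 10 for a stable fit")

    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        logger.warning("constant output: all ANCOVA shares set to 0")
        shares = pd.Series(0.0, index=list(groups))
        return AncovaReport(shares=shares, r_squared=0.0, residual=1.0, ss_type=ss_type)

    X = inputs[all_cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - X.mean(axis=0)) / sd  # shares invariant to affine input rescaling
    col_idx = {c: i for i, c in enumerate(all_cols)}

    full_ess = _explained_ss(y, Xs)
    r2 = full_ess / tss

    shares = {}
    if ss_type == "marginal":
        for name, cols in groups.items():
            drop = [col_idx[c] for c in cols]
            keep = [i for i in range(len(all_cols)) if i not in drop]
            shares[name] = (full_ess - _explained_ss(y, Xs[:, keep])) / tss
    else:
        prev_ess = 0.0
        taken: list[int] = []
        for name, cols in groups.items():
            taken.extend(col_idx[c] for c in cols)
            ess = _explained_ss(y, Xs[:, taken])
            shares[name] = (ess - prev_ess) / tss
            prev_ess = ess

    shares = pd.Series(shares).clip(lower=0.0)
    return AncovaReport(
        shares=shares,
        r_squared=float(r2),
        residual=float(1.0 - r2),
        ss_type=ss_type,
        metadata={"n": len(y), "n_columns": len(all_cols)},
    )


def ancova_report(
    psa,
    groups: dict | None = None,
    quantities: tuple = ("inhb", "delta"),
    ss_type: str = "marginal",
) -> pd.DataFrame:
    """Tidy ANCOVA table over every comparison and output quantity of a PSA."""
    from .voi import default_parameter_groups

    if groups is None:
        groups = default_parameter_groups(psa.inputs.columns)
    rows = []
    for comparison in psa.comparisons:
        for quantity in quantities:
            rep = ancova_decompose(
                psa.output(comparison, quantity), psa.inputs, groups, ss_type=ss_type
            )
            for gname, share in rep.shares.items():
                rows.append(
                    {
                        "output": quantity,
                        "comparison": comparison,
                        "group": gname,
                        "share": float(share),
                        "r_squared": rep.r_squared,
                    }
                )
    return pd.DataFrame(rows)
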