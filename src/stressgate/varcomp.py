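"""Line/error variance components and the line percentage per trait x environment.

The model is the one-way random-effects decomposition for replicated inbred
lines within one environment,

    value_ij = mu + line_i + eps_ij,    line_i ~ N(0, v_line),  eps ~ N(0, v_error),

fitted by REML (component estimates truncated at zero at the boundary) with a
method-of-moments fallback based on expected mean squares, which handles
unbalanced replication through the effective per-line replicate number
n0 = (N - sum n_i^2 / N) / (k - 1).

The "line percentage" 100 * v_line / (v_line + v_error) is the share of
phenotypic variance attributable to genotype (broad-sense heritability of a
single observation).  It is undefined (reported blank) when v_line = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    ENVIRONMENTS,
    InsufficientDataError,
    InvalidArgumentError,
    PhenotypeTable,
)

__all__ = ["VarianceComponents", "estimate_components", "line_pct", "components_table"]

# Relative threshold below which an estimated line component is treated as a
# boundary zero (REML optimizers return tiny positive values at the boundary).
_ZERO_REL_TOL = 1e-7


@dataclass(frozen=True)
class VarianceComponents:
    """Line and error variance components; ``line_pct`` is None when v_line = 0."""

    v_line: float
    v_error: float

    @property
    def line_pct(self) -> Optional[float]:
        if self.v_line == 0.0 and self.v_error == 0.0:
            return None
        return line_pct(self.v_line, self.v_error)


def line_pct(v_line: float, v_error: float) -> Optional[float]:
    """100 * v_line / (v_line + v_error); None (blank) when v_line = 0.

    Raises when both components are zero (the ratio is undefined in a
    stronger sense: there is no variance to apportion).
    """
    if v_line < 0 or v_error < 0:
        raise InvalidArgumentError("variance components must be >= 0")
    if v_line == 0 and v_error == 0:
        raise InvalidArgumentError("line percentage undefined when both components are zero")
    if v_line == 0:
        return None
    return 100.0 * v_line / (v_line + v_error)


def _moments_estimate(values: np.ndarray, lines: np.ndarray) -> tuple[float, float]:
    """Expected-mean-squares estimator, unbalanced-design n0 coefficient."""
    df = pd.DataFrame({"y": values, "line": lines})
    groups = df.groupby("line")["y"]
    k = groups.ngroups
    n_i = groups.count().to_numpy(dtype=float)
    N = n_i.sum()
    grand = df["y"].mean()
    means = groups.mean().to_numpy()
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ss_within = float(((df["y"] - groups.transform("mean")) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    v_line = max((ms_between - ms_within) / n0, 0.0)
    return v_line, ms_within


def _reml_estimate(values: np.ndarray, lines: np.ndarray) -> tuple[float, float]:
    import statsmodels.api as sm

    exog = np.ones((len(values), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(values, exog, groups=pd.Series(lines))
        fit = model.fit(reml=True)
    v_line = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
    v_error = max(float(fit.scale), 0.0)
    return v_line, v_error


def estimate_components(
    pheno: PhenotypeTable,
    trait: str,
    environment: str,
    method: str = "reml",
) -> VarianceComponents:
    """Estimate (v_line, v_error) for one trait in one environment.

    ``method`` is ``"reml"`` (default; falls back to moments if the
    optimizer fails) or ``"moments"``.
    """
    if environment not in ENVIRONMENTS:
        raise InvalidArgumentError(f"unknown environment {environment!r}")
    if method not in ("reml", "moments"):
        raise InvalidArgumentError(f"method must be 'reml' or 'moments', got {method!r}")
    d = pheno.subset(trait, environment)
    counts = d.groupby("line_id")["value"].count()
    if (counts >= 2).sum() < 2:
        raise InsufficientDataError(
            "need >= 2 lines with >= 2 replicates each "
            f"(trait {trait!r}, environment {environment!r})"
        )
    values = d["value"].to_numpy()
    lines = d["line_id"].to_numpy()
    if method == "reml":
        try:
            v_line, v_error = _reml_estimate(values, lines)
        except Exception:
            v_line, v_error = _moments_estimate(values, lines)
    else:
        v_line, v_error = _moments_estimate(values, lines)
    # Truncate boundary-noise line components to an exact zero so that the
    # line percentage is reported blank, as for a zero component.
    if v_line <= _ZERO_REL_TOL * (v_line + v_error):
        v_line = 0.0
    return VarianceComponents(v_line=v_line, v_error=v_error)


def components_table(pheno: PhenotypeTable, method: str = "reml") -> pd.DataFrame:
    """Variance components for every trait x environment with replication.

    One row per environment; three columns per trait (v_line, v_error,
    line_pct), mirroring the conventional per-environment heritability table.
    Cells without sufficient replication are NaN.
    """
    rows = []
    for env in ENVIRONMENTS:
        row: dict[str, object] = {"environment": env}
        for trait in pheno.traits:
            try:
                vc = estimate_components(pheno, trait, env, method=method)
                row[f"{trait}:v_line"] = vc.v_line
                row[f"{trait}:v_error"] = vc.v_error
                row[f"{trait}:line_pct"] = np.nan if vc.line_pct is None else round(vc.line_pct, 1)
            except InsufficientDataError:
                row[f"{trait}:v_line"] = np.nan
                row[f"{trait}:v_error"] = np.nan
                row[f"{trait}:line_pct"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
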