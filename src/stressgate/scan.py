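"""Single-marker genotype x environment scan for biparental populations.

For each marker the fixed-effects linear model

    value ~ block(environment) + environment + allele + allele:environment

is fitted by least squares with sum-to-zero contrasts, and the type-III
F-test P value for the allele:environment interaction is recorded.  Blocks
are coded within environment (block + block:environment) because replicate
blocks are month-replicates crossed with treatments; block x marker
interactions are pooled into the error term.

Allele effects per environment are least-squares means expressed as
deviations from the environment population mean (half-differences): for a
balanced design effect(A, env) = -effect(B, env), negative estimates meaning
the allele confers less growth than average.  "Significant" means the 95%
confidence interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ENVIRONMENTS,
    GeneticMap,
    GenotypeTable,
    InsufficientDataError,
    InvalidArgumentError,
    PhenotypeTable,
)

__all__ = ["ScanResult", "scan_interaction", "allele_effects", "coinheritance_check"]

# Effects smaller than this are treated as exact zeros when a model fits the
# data perfectly (zero residual variance, e.g. noiseless simulations).
_EFFECT_ATOL = 1e-9
_SSE_REL_TOL = 1e-10


@dataclass(frozen=True)
class ScanResult:
    """Per-marker scan table.

    Columns: marker, chrom, pos_cM, bin, raw_p, main_p, note, then
    ``effect_<env>``, ``se_<env>``, ``ci_lo_<env>``, ``ci_hi_<env>``,
    ``sig_<env>`` for each environment (allele-A deviations; allele B is the
    negation).  ``smoothed_p`` and ``q_value`` are filled by the smoothing
    stage and are NaN here.
    """

    table: pd.DataFrame

    def significant_markers(self, alpha: float = 0.05, on: str = "q_value") -> list[str]:
        col = self.table[on]
        return list(self.table.loc[col < alpha, "marker"])


def _sum_coded(values: np.ndarray, levels: Sequence) -> np.ndarray:
    """Sum-to-zero (deviation) coding: one column per non-reference level."""
    levels = list(levels)
    cols = []
    last = levels[-1]
    for lev in levels[:-1]:
        c = np.where(values == lev, 1.0, np.where(values == last, -1.0, 0.0))
        cols.append(c)
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def _interaction_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ik->ijk", a, b).reshape(len(a), -1)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of the design."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _base_design(d: pd.DataFrame) -> np.ndarray:
    env = d["environment"].to_numpy()
    block = d["block"].to_numpy()
    envs = [e for e in ENVIRONMENTS if e in set(env)]
    blocks = sorted(set(block))
    E = _sum_coded(env, envs)
    B = _sum_coded(block, blocks)
    parts = [np.ones((len(d), 1)), B, E]
    if E.shape[1] and B.shape[1]:
        parts.append(_interaction_cols(E, B))
    return np.column_stack(parts), E


def _marker_frame(geno: GenotypeTable, pheno: PhenotypeTable, trait: str) -> pd.DataFrame:
    d = pheno.subset(trait)
    if len(d) == 0:
        raise InvalidArgumentError(f"no phenotype records for trait {trait!r}")
    return d


def scan_interaction(
    geno: GenotypeTable,
    pheno: PhenotypeTable,
    trait: str,
    gmap: Optional[GeneticMap] = None,
    ci_level: float = 0.95,
) -> ScanResult:
    """Genome scan: interaction P value and per-environment effects per marker.

    Markers whose minor allele class has fewer than two lines are flagged
    (``note`` column) and reported with missing P values rather than raising.
    """
    d = _marker_frame(geno, pheno, trait)
    if d["environment"].nunique() < 2:
        raise InvalidArgumentError("need >= 2 environments for an interaction scan")
    signs = geno.signs()
    rows = []
    for marker in geno.marker_names:
        res = _scan_one(d, signs[marker], marker, ci_level)
        rows.append(res)
    tab = pd.DataFrame(rows)
    tab["smoothed_p"] = np.nan
    tab["q_value"] = np.nan
    if gmap is not None:
        tab = tab.merge(gmap.table, on="marker", how="left")
        tab = tab.sort_values(["chrom", "pos_cM"], kind="stable").reset_index(drop=True)
    else:
        tab["chrom"] = np.nan
        tab["pos_cM"] = np.nan
        tab["bin"] = ""
    lead = ["marker", "chrom", "pos_cM", "bin", "raw_p", "smoothed_p", "q_value", "main_p", "note"]
    tab = tab[lead + [c for c in tab.columns if c not in lead]]
    return ScanResult(tab)


def _scan_one(d: pd.DataFrame, sign_col: pd.Series, marker: str, ci_level: float) -> dict:
    s_all = d["line_id"].map(sign_col)
    keep = s_all.notna() & d["value"].notna()
    dd = d[keep]
    s = s_all[keep].to_numpy(dtype=float)
    out: dict[str, object] = {"marker": marker, "raw_p": np.nan, "main_p": np.nan, "note": ""}
    n_lines_per_class = dd.groupby(s_all[keep])["line_id"].nunique() if len(dd) else pd.Series(dtype=int)
    if len(n_lines_per_class) < 2 or (n_lines_per_class < 2).any():
        out["note"] = "monomorphic"
        for env in ENVIRONMENTS:
            for c in ("effect", "se", "ci_lo", "ci_hi"):
                out[f"{c}_{env}"] = np.nan
            out[f"sig_{env}"] = False
        return out
    y = dd["value"].to_numpy(dtype=float)
    X_base, E = _base_design(dd)
    s_col = s[:, None]
    SE = s_col * E  # allele x environment interaction columns
    full = np.column_stack([X_base, s_col, SE])
    sse_full, rank_full = _rss(full, y)
    dfe = len(y) - rank_full
    tot = float(((y - y.mean()) ** 2).sum()) or 1.0
    for label, reduced in (("raw_p", np.column_stack([X_base, s_col])),
                           ("main_p", np.column_stack([X_base, SE]))):
        sse_red, rank_red = _rss(reduced, y)
        q = rank_full - rank_red
        if q <= 0 or dfe <= 0:
            continue
        num = max(sse_red - sse_full, 0.0)
        if sse_full <= _SSE_REL_TOL * tot:
            out[label] = 0.0 if num > _SSE_REL_TOL * tot else np.nan
        else:
            F = (num / q) / (sse_full / dfe)
            out[label] = float(stats.f.sf(F, q, dfe))
    eff = _effects_frame(dd, s, ci_level)
    for env in ENVIRONMENTS:
        if env in eff.index:
            r = eff.loc[env]
            out[f"effect_{env}"] = r["effect"]
            out[f"se_{env}"] = r["se"]
            out[f"ci_lo_{env}"] = r["ci_lo"]
            out[f"ci_hi_{env}"] = r["ci_hi"]
            out[f"sig_{env}"] = bool(r["significant"])
        else:
            for c in ("effect", "se", "ci_lo", "ci_hi"):
                out[f"{c}_{env}"] = np.nan
            out[f"sig_{env}"] = False
    return out


def _effects_frame(dd: pd.DataFrame, s: np.ndarray, ci_level: float) -> pd.DataFrame:
    """Per-environment allele-A effect, SE and CI from env-specific OLS."""
    rows = {}
    env_arr = dd["environment"].to_numpy()
    block_arr = dd["block"].to_numpy()
    y_all = dd["value"].to_numpy(dtype=float)
    for env in ENVIRONMENTS:
        m = env_arr == env
        if m.sum() == 0:
            continue
        y = y_all[m]
        se_s = s[m]
        if len(np.unique(se_s)) < 2:
            rows[env] = {"effect": np.nan, "se": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "significant": False}
            continue
        B = _sum_coded(block_arr[m], sorted(set(block_arr[m])))
        X = np.column_stack([np.ones(m.sum()), B, se_s])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dfe = len(y) - rank
        sse = float(resid @ resid)
        effect = float(beta[-1])
        if dfe <= 0:
            rows[env] = {"effect": effect, "se": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "significant": False}
            continue
        sigma2 = sse / dfe
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = float(np.sqrt(max(sigma2 * XtX_inv[-1, -1], 0.0)))
        tq = stats.t.ppf(0.5 + ci_level / 2.0, dfe)
        lo, hi = effect - tq * se, effect + tq * se
        sig = (lo > _EFFECT_ATOL) or (hi < -_EFFECT_ATOL)
        rows[env] = {"effect": effect, "se": se, "ci_lo": lo, "ci_hi": hi, "significant": sig}
    return pd.DataFrame(rows).T


def allele_effects(
    geno: GenotypeTable,
    pheno: PhenotypeTable,
    trait: str,
    marker: str,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-environment allele effects with SE and CI at one marker.

    Returns a DataFrame indexed by environment with columns ``effect``
    (allele-A deviation from the environment mean; allele B is the
    negation), ``se``, ``ci_lo``, ``ci_hi``, ``significant``.
    """
    if marker not in geno.marker_names:
        raise InvalidArgumentError(f"marker {marker!r} not in genotype table")
    d = _marker_frame(geno, pheno, trait)
    s_all = d["line_id"].map(geno.signs()[marker])
    keep = s_all.notna() & d["value"].notna()
    dd, s = d[keep], s_all[keep].to_numpy(dtype=float)
    if len(np.unique(s)) < 2:
        raise InvalidArgumentError(f"marker {marker!r} is monomorphic in the phenotyped lines")
    return _effects_frame(dd, s, ci_level)


def interaction_variance(
    geno: GenotypeTable,
    pheno: PhenotypeTable,
    trait: str,
    marker: str,
) -> float:
    """Diagnostic: variance of the allele x environment effect when fitted
    as random.

    Treating the environment-specific allele effect as a random slope, its
    variance is estimated by moments from the per-environment least-squares
    effects: Var_env(effect) minus the mean squared SE (sampling noise),
    truncated at zero.  The fixed-effects F-test of :func:`scan_interaction`
    remains the primary interaction statistic; this component is for
    comparing interaction magnitudes across markers, with only four
    environments it is a coarse summary.
    """
    eff = allele_effects(geno, pheno, trait, marker)
    ok = eff["effect"].notna() & eff["se"].notna()
    if ok.sum() < 2:
        raise InsufficientDataError(f"marker {marker!r}: effects estimable in < 2 environments")
    est = eff.loc[ok, "effect"].to_numpy(dtype=float)
    se = eff.loc[ok, "se"].to_numpy(dtype=float)
    return max(float(np.var(est, ddof=1) - np.mean(se**2)), 0.0)


def coinheritance_check(
    geno: GenotypeTable,
    significant_markers: Sequence[str],
    gmap: GeneticMap,
    threshold: float = 0.5,
) -> list[tuple[str, str, float]]:
    """Flag pairs of significant markers on *different* chromosomes whose
    genotype vectors are correlated beyond ``threshold`` (|r|), a screen for
    artificial coinheritance.  Returns (marker_a, marker_b, r) tuples.
    """
    markers = [m for m in significant_markers if m in geno.marker_names]
    if len(markers) < 2:
        return []
    pos = gmap.positions_of(markers)
    S = geno.signs()[markers]
    flagged = []
    for i, a in enumerate(markers):
        for b in markers[i + 1:]:
            if pos.loc[a, "chrom"] == pos.loc[b, "chrom"]:
                continue
            pair = S[[a, b]].dropna()
            if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                continue
            r = float(np.corrcoef(pair[a], pair[b])[0, 1])
            if abs(r) > threshold:
                flagged.append((a, b, r))
    return flagged
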