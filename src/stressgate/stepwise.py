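"""Joint forward stepwise marker selection for multiparent (NAM-like) designs,
and the simulation study that calibrates the entry threshold (SLE).

The model is fitted jointly across families.  The base model contains
family, environment, block and block-within-environment fixed effects.  A
candidate term for marker m contributes family-nested allele columns
s_m * 1[family = f] plus their environment interactions
s_m * 1[family = f] * env (sum-coded), i.e. family-specific allele effects
with no allelic-series constraint.  At each step the candidate with the
smallest joint F-test P value (conditional on the current model) enters if
P < SLE; selection stops when no candidate passes or max_terms is reached.

Calibration places five QTL of decreasing variance targets at random
markers, simulates phenotypes, runs the selection at each SLE on a grid,
and scores selected markers against the truth: a selected marker within
``tp_window`` cM of a still-unclaimed true QTL (same chromosome) is a true
positive, each true QTL credited at most once (in entry order); all other
selections are false positives; unclaimed QTL are false negatives.
PPV = TP/(TP+FP), sensitivity = TP/(TP+FN), FDR = 1 - PPV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
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
    TrueArchitecture,
)
from .scan import _sum_coded, _interaction_cols
from .simulate import place_random_qtl, simulate_nam_genotypes, simulate_phenotypes

__all__ = [
    "StepwiseConfig",
    "NamDesign",
    "StepwiseResult",
    "joint_stepwise",
    "calibrate_sle",
    "score_selection",
    "best_sle",
    "BestSLE",
]

_EIG_RTOL = 1e-9


@dataclass(frozen=True)
class StepwiseConfig:
    """Entry threshold and stopping rules for forward selection."""

    sle: float = 0.001
    max_terms: int = 20
    tp_window: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sle < 1.0:
            raise InvalidArgumentError("sle must be in [0, 1)")
        if self.max_terms < 0:
            raise InvalidArgumentError("max_terms must be >= 0")
        if self.tp_window < 0:
            raise InvalidArgumentError("tp_window must be >= 0")


@dataclass(frozen=True)
class NamDesign:
    """Population and noise structure for the calibration simulations."""

    n_families: int = 5
    lines_per_family: int = 50
    n_blocks: int = 2
    trait_mean: float = 10.0
    block_sd: float = 0.5
    residual_sd: float = 1.0
    gate: str = "independent"


@dataclass
class StepwiseResult:
    """Outcome of one forward-selection run.

    ``entries`` has one row per accepted term: step, marker, p_entry.
    ``path`` additionally records, for every evaluated step, the best
    candidate and its P value (used to replay the same selection at a
    smaller entry threshold without refitting).
    """

    entries: pd.DataFrame
    path: pd.DataFrame
    config: StepwiseConfig
    _effects: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def selected_markers(self) -> list[str]:
        return list(self.entries["marker"])

    def selected_at(self, sle: float) -> list[str]:
        """Markers that would have been selected with entry threshold ``sle``.

        Valid for sle <= the threshold used for the run: forward selection
        is greedy on the minimum candidate P, so a smaller threshold stops
        at the first step whose entry P fails it and selects a prefix.
        """
        out = []
        for _, row in self.path.iterrows():
            if not (row["p_entry"] < sle):
                break
            out.append(row["marker"])
        return out

    def effect_table(self) -> Optional[pd.DataFrame]:
        """Per (marker, family, environment) allele-A effect and SE from the
        final model fit; None when nothing was selected."""
        return self._effects


def _design_pieces(geno: GenotypeTable, pheno: PhenotypeTable, trait: str):
    d = pheno.subset(trait)
    if d["environment"].nunique() < 2:
        raise InvalidArgumentError("need >= 2 environments")
    families = list(geno.families)
    if len(families) < 2:
        raise InvalidArgumentError("joint stepwise requires >= 2 families")
    line_pos = geno.line_ids.get_indexer(d["line_id"])
    if (line_pos < 0).any():
        missing = d.loc[line_pos < 0, "line_id"].iloc[0]
        raise InvalidArgumentError(f"phenotyped line {missing!r} absent from genotype table")
    S = geno.signs().to_numpy(dtype=float)
    G = S[line_pos, :]
    G = np.nan_to_num(G, nan=0.0)  # missing genotype -> allele-mean (0) predictor
    if (G == G[0]).all():
        raise InsufficientDataError("no polymorphic markers")
    env = d["environment"].to_numpy()
    fam = d["family"].to_numpy()
    block = d["block"].to_numpy()
    envs = [e for e in ENVIRONMENTS if e in set(env)]
    E = _sum_coded(env, envs)
    Bk = _sum_coded(block, sorted(set(block)))
    Fm = np.column_stack([(fam == f).astype(float) for f in families])
    base = [np.ones((len(d), 1)), _sum_coded(fam, families), E, Bk]
    if E.shape[1] and Bk.shape[1]:
        base.append(_interaction_cols(E, Bk))
    X_base = np.column_stack(base)
    # Shared per-marker dummy structure: family indicators then family x env.
    D = np.column_stack([Fm, _interaction_cols(Fm, E)]) if E.shape[1] else Fm
    y = d["value"].to_numpy(dtype=float)
    return d, G, D, X_base, y, families, envs, E


def _candidate_pvalues(Q, r, sse, dfe, G, D, E_const, exclude):
    """Joint F-test P value of each candidate marker term given the model.

    Q: orthonormal basis of the current model; r: current residual;
    E_const: D^T D when genotypes have no zeros, else None.
    """
    n, K = D.shape[0], D.shape[1]
    M = G.shape[1]
    A = np.empty((K, Q.shape[1], M))
    for j in range(K):
        A[j] = (Q * D[:, j][:, None]).T @ G
    B = (D * r[:, None]).T @ G  # (K, M)
    if E_const is not None:
        E_all = np.broadcast_to(E_const, (M, K, K))
    else:
        W = G * G
        DD = D[:, :, None] * D[:, None, :]
        E_all = np.einsum("nm,njk->mjk", W, DD)
    AtA = np.einsum("jpm,kpm->mjk", A, A)
    Mm = E_all - AtA
    evals, evecs = np.linalg.eigh(Mm)
    lmax = evals[:, -1]
    tol = np.maximum(lmax, 0.0)[:, None] * K * _EIG_RTOL + 1e-300
    good = evals > tol
    bT = np.einsum("km,mkq->mq", B, evecs)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(good, bT**2 / evals, 0.0)
    ssr = contrib.sum(axis=1)
    qdf = good.sum(axis=1)
    pvals = np.full(M, np.nan)
    ok = (qdf > 0) & (dfe - qdf > 0)
    ssr = np.minimum(ssr, sse)  # numeric guard
    denom = (sse - ssr[ok]) / (dfe - qdf[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        Fv = np.where(denom > 0, (ssr[ok] / qdf[ok]) / denom, np.inf)
    pvals[ok] = stats.f.sf(Fv, qdf[ok], (dfe - qdf)[ok])
    pvals[list(exclude)] = np.nan
    return pvals, qdf


def joint_stepwise(
    geno: GenotypeTable,
    pheno: PhenotypeTable,
    trait: str,
    cfg: StepwiseConfig = StepwiseConfig(),
) -> StepwiseResult:
    """Forward joint stepwise selection of marker(family) x treatment terms."""
    d, G, D, X_base, y, families, envs, E = _design_pieces(geno, pheno, trait)
    marker_names = list(geno.marker_names)
    X = X_base
    Q, _ = np.linalg.qr(X)
    r = y - Q @ (Q.T @ y)
    sse = float(r @ r)
    rank = Q.shape[1]
    dfe = len(y) - rank
    no_zero = not (G == 0).any()
    E_const = D.T @ D if no_zero else None
    entries, path = [], []
    chosen: list[int] = []
    step = 0
    while step < cfg.max_terms:
        pvals, _ = _candidate_pvalues(Q, r, sse, dfe, G, D, E_const, chosen)
        if np.isnan(pvals).all():
            break
        best = int(np.nanargmin(pvals))
        p_best = float(pvals[best])
        path.append({"step": step + 1, "marker": marker_names[best], "p_entry": p_best})
        if not (p_best < cfg.sle):
            break
        chosen.append(best)
        entries.append({"step": step + 1, "marker": marker_names[best], "p_entry": p_best})
        cols = G[:, best][:, None] * D
        X = np.column_stack([X, cols])
        Q, _ = np.linalg.qr(X)
        r = y - Q @ (Q.T @ y)
        sse = float(r @ r)
        rank = np.linalg.matrix_rank(X) if X.shape[1] > len(y) else Q.shape[1]
        dfe = len(y) - rank
        step += 1
    entries_df = pd.DataFrame(entries, columns=["step", "marker", "p_entry"])
    path_df = pd.DataFrame(path, columns=["step", "marker", "p_entry"])
    effects = None
    if chosen:
        effects = _final_effects(X, X_base, y, D, G, chosen, marker_names, families, envs, E)
    return StepwiseResult(entries=entries_df, path=path_df, config=cfg, _effects=effects)


def _final_effects(X, X_base, y, D, G, chosen, marker_names, families, envs, E):
    """Allele-A effect +/- SE per (marker, family, environment) in the final fit."""
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dfe = len(y) - int(np.linalg.matrix_rank(X))
    sigma2 = float(resid @ resid) / dfe if dfe > 0 else np.nan
    p0 = X_base.shape[1]
    K = D.shape[1]
    nf = len(families)
    rows = []
    env_codes = {e: _sum_coded(np.array([e]), envs)[0] for e in envs}
    n_env_cols = len(envs) - 1
    for t_idx, m_idx in enumerate(chosen):
        off = p0 + t_idx * K
        for fi, famname in enumerate(families):
            for env in envs:
                c = np.zeros(X.shape[1])
                c[off + fi] = 1.0
                code = env_codes[env]
                # interaction block is family-major: column nf + fi*n_env_cols + li
                for li, cl in enumerate(code):
                    c[off + nf + fi * n_env_cols + li] = cl
                eff = float(c @ beta)
                se = float(np.sqrt(max(sigma2 * (c @ XtX_inv @ c), 0.0))) if dfe > 0 else np.nan
                rows.append(
                    {
                        "marker": marker_names[m_idx],
                        "family": famname,
                        "environment": env,
                        "effect": eff,
                        "se": se,
                    }
                )
    return pd.DataFrame(rows)


def score_selection(
    selected: Sequence[str],
    truth: TrueArchitecture,
    gmap: GeneticMap,
    tp_window: float = 10.0,
) -> tuple[int, int, int]:
    """(TP, FP, FN) for one simulation, crediting each true QTL at most once.

    Selected markers are processed in entry order; one within ``tp_window``
    cM of an unclaimed true QTL on the same chromosome claims it.
    """
    truth_pos = gmap.positions_of([q.marker for q in truth.qtl])
    unclaimed = list(range(len(truth.qtl)))
    tp = fp = 0
    if len(selected) > 0:
        sel_pos = gmap.positions_of(list(selected))
        for _, row in sel_pos.iterrows():
            best_j, best_d = None, np.inf
            for j in unclaimed:
                trow = truth_pos.iloc[j]
                if trow["chrom"] != row["chrom"]:
                    continue
                dist = abs(trow["pos_cM"] - row["pos_cM"])
                if dist <= tp_window and dist < best_d:
                    best_j, best_d = j, dist
            if best_j is not None:
                tp += 1
                unclaimed.remove(best_j)
            else:
                fp += 1
    fn = len(unclaimed)
    return tp, fp, fn


@dataclass(frozen=True)
class BestSLE:
    sle: float
    meets_constraint: bool


def calibrate_sle(
    gmap: GeneticMap,
    design: NamDesign,
    r2_targets: Sequence[float],
    sle_grid: Sequence[float],
    n_sims: int,
    seed: Optional[int] = None,
    tp_window: float = 10.0,
    max_terms: int = 20,
    trait: str = "trait",
) -> pd.DataFrame:
    """Simulation calibration of the stepwise entry threshold.

    One NAM genotype panel is simulated and reused across simulations (the
    marker set and population structure are the fixed experimental design);
    each simulation draws fresh QTL positions and phenotypes.  Selection is
    run once per simulation at the loosest grid threshold and replayed at
    the tighter ones.  Returns a tidy frame: sle, tp, fp, fn, ppv,
    sensitivity, fdr (NaN sensitivity when no true positives are possible).
    """
    if n_sims < 1:
        raise InvalidArgumentError("n_sims must be >= 1")
    grid = sorted(set(float(s) for s in sle_grid))
    if not grid:
        raise InvalidArgumentError("sle grid must be nonempty")
    ss = np.random.SeedSequence(seed)
    geno_ss, *sim_ss = ss.spawn(n_sims + 1)
    geno = simulate_nam_genotypes(
        gmap, design.n_families, design.lines_per_family, seed=geno_ss
    )
    counts = {s: np.zeros(3, dtype=int) for s in grid}
    loosest = max(grid)
    run_cfg = StepwiseConfig(sle=loosest, max_terms=max_terms, tp_window=tp_window)
    for sim in range(n_sims):
        rng = np.random.default_rng(sim_ss[sim])
        arch = place_random_qtl(
            gmap,
            r2_targets,
            design.residual_sd,
            rng,
            gate=design.gate,
            mode="marginal",
            trait_mean=design.trait_mean,
            block_sd=design.block_sd,
        )
        pheno = simulate_phenotypes(
            geno, arch, n_blocks=design.n_blocks,
            seed=rng.integers(0, 2**31 - 1), trait=trait,
        )
        res = joint_stepwise(geno, pheno, trait, run_cfg)
        for s in grid:
            sel = res.selected_at(s)
            tp, fp, fn = score_selection(sel, arch, gmap, tp_window=tp_window)
            counts[s] += (tp, fp, fn)
    rows = []
    for s in grid:
        tp, fp, fn = (int(v) for v in counts[s])
        ppv = tp / (tp + fp) if tp + fp > 0 else np.nan
        sens = tp / (tp + fn) if tp + fn > 0 else np.nan
        rows.append(
            {
                "sle": s,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "ppv": ppv,
                "sensitivity": sens,
                "fdr": 1.0 - ppv if not np.isnan(ppv) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def best_sle(calibration: pd.DataFrame, max_fdr: float = 0.10) -> BestSLE:
    """Grid value maximising sensitivity subject to FDR <= ``max_fdr``.

    Ties break toward the smaller (stricter) threshold.  When no grid point
    satisfies the constraint, the point with the smallest FDR is returned
    with ``meets_constraint=False``.
    """
    if len(calibration) == 0:
        raise InvalidArgumentError("empty calibration")
    cal = calibration.sort_values("sle").reset_index(drop=True)
    ok = cal[cal["fdr"] <= max_fdr]
    if len(ok) > 0:
        best = ok.sort_values(["sensitivity", "sle"], ascending=[False, True]).iloc[0]
        return BestSLE(sle=float(best["sle"]), meets_constraint=True)
    best = cal.sort_values(["fdr", "sle"]).iloc[0]
    return BestSLE(sle=float(best["sle"]), meets_constraint=False)
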