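"""P-value smoothing along the genetic map, FDR control, and QTL calling.

Adjacent-marker combination borrows strength from linked markers: each
marker's P value is combined with its neighbours in a sliding window that
never spans a chromosome boundary (edge windows shrink symmetrically).  Two
combination statistics are provided: Simes, min_k (w * p_(k) / k) capped at
1, and Fisher, P(chi^2_{2w} >= -2 sum ln p).  Benjamini-Hochberg q-values
are then computed on the smoothed values and maximal runs of markers below
the FDR threshold are merged into QTL intervals.

A fractional-rank pre-transform (rank / (n+1), average ranks for ties) is
available for scans whose raw P values are unreliable in distribution.  It
is off by default: ranks bound the smallest achievable value at ~1/(n+1),
so rank-transformed and smoothed values can never survive BH correction at
conventional FDR levels — the transform is a robustness device for
*ordering* markers, not for calibrated significance (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneticMap, GenotypeTable, InvalidArgumentError
from .scan import ScanResult

__all__ = [
    "SmoothingConfig",
    "fractional_ranks",
    "smooth_pvalues",
    "bh_fdr",
    "cluster_markers",
    "call_qtl",
    "add_smoothing",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Parameters of the smoothing / FDR stage.

    window must be odd so every marker is the centre of its window.
    """

    window: int = 3
    method: str = "simes"
    fdr_alpha: float = 0.05
    cluster_r2: float = 0.9
    rank_transform: bool = False

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise InvalidArgumentError("window must be an odd integer >= 1")
        if self.method not in ("simes", "fisher"):
            raise InvalidArgumentError("method must be 'simes' or 'fisher'")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise InvalidArgumentError("fdr_alpha must be in (0, 1)")
        if not 0.0 < self.cluster_r2 <= 1.0:
            raise InvalidArgumentError("cluster_r2 must be in (0, 1]")


def _validate_pvals(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("empty P-value list")
    if np.isnan(p).any():
        raise InvalidArgumentError("missing P values are not allowed here")
    if ((p < 0) | (p > 1)).any():
        raise InvalidArgumentError("P values must lie in [0, 1]")
    return p


def fractional_ranks(pvals: Sequence[float]) -> np.ndarray:
    """rank_i / (n + 1), with average ranks for ties; order-preserving."""
    p = _validate_pvals(pvals)
    return stats.rankdata(p, method="average") / (p.size + 1)


def _combine(window_vals: np.ndarray, method: str) -> float:
    w = window_vals.size
    if method == "simes":
        srt = np.sort(window_vals)
        return float(min(np.min(w * srt / np.arange(1, w + 1)), 1.0))
    with np.errstate(divide="ignore"):
        stat = -2.0 * np.sum(np.log(window_vals))
    return float(stats.chi2.sf(stat, 2 * w))


def smooth_pvalues(
    pvals: Sequence[float],
    chrom: Sequence[int],
    cfg: SmoothingConfig,
) -> np.ndarray:
    """Combine each marker's P value with its within-chromosome neighbours.

    ``pvals`` must be aligned to markers sorted by (chromosome, position);
    passing unsorted chromosomes raises rather than silently sorting.
    Windows shrink symmetrically at chromosome ends.
    """
    p = _validate_pvals(pvals)
    chrom = np.asarray(list(chrom))
    if chrom.size != p.size:
        raise InvalidArgumentError("pvals and chrom must align")
    # chromosomes must form contiguous runs
    change = np.flatnonzero(np.diff(chrom) != 0)
    seen = set()
    prev = None
    for c in chrom:
        if c != prev:
            if c in seen:
                raise InvalidArgumentError("markers are not sorted by chromosome")
            seen.add(c)
            prev = c
    if cfg.rank_transform:
        p = fractional_ranks(p)
    out = np.empty_like(p)
    half = cfg.window // 2
    bounds = np.concatenate([[0], change + 1, [p.size]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        for i in range(s, e):
            h = min(half, i - s, e - 1 - i)
            out[i] = _combine(p[i - h: i + h + 1], cfg.method)
    return out


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    p = _validate_pvals(pvals)
    return multipletests(p, method="fdr_bh")[1]


def add_smoothing(scan: ScanResult, gmap: GeneticMap, cfg: SmoothingConfig) -> ScanResult:
    """Fill the ``smoothed_p`` and ``q_value`` columns of a scan result.

    Markers with missing raw P (e.g. monomorphic) are excluded from windows
    and keep missing smoothed/q values.
    """
    tab = scan.table.copy()
    order = gmap.table["marker"].tolist()
    if list(tab["marker"]) != order:
        tab = tab.set_index("marker").loc[order].reset_index()
    ok = tab["raw_p"].notna().to_numpy()
    sm = np.full(len(tab), np.nan)
    if ok.any():
        sm[ok] = smooth_pvalues(
            tab.loc[ok, "raw_p"].to_numpy(), gmap.table.loc[ok, "chrom"].to_numpy(), cfg
        )
    q = np.full(len(tab), np.nan)
    if ok.any():
        q[ok] = bh_fdr(sm[ok])
    tab["smoothed_p"] = sm
    tab["q_value"] = q
    tab["chrom"] = gmap.table["chrom"].to_numpy()
    tab["pos_cM"] = gmap.table["pos_cM"].to_numpy()
    tab["bin"] = gmap.table["bin"].to_numpy()
    return ScanResult(tab)


def cluster_markers(
    geno: GenotypeTable,
    gmap: GeneticMap,
    cluster_r2: float = 0.9,
) -> list[dict]:
    """Greedy merge of map-adjacent markers with genotype r^2 >= threshold.

    Returns one dict per cluster: ``{"representative", "members", "chrom"}``.
    The representative is the most complete member (fewest missing calls),
    ties broken by map order.
    """
    if not 0.0 < cluster_r2 <= 1.0:
        raise InvalidArgumentError("cluster_r2 must be in (0, 1]")
    S = geno.signs()
    clusters: list[dict] = []
    for c in gmap.chromosomes:
        markers = gmap.table.loc[gmap.table["chrom"] == c, "marker"].tolist()
        current = [markers[0]]
        for prev, m in zip(markers[:-1], markers[1:]):
            pair = S[[prev, m]].dropna()
            r2 = 0.0
            if len(pair) >= 2 and pair[prev].std() > 0 and pair[m].std() > 0:
                r2 = float(np.corrcoef(pair[prev], pair[m])[0, 1] ** 2)
            if r2 >= cluster_r2:
                current.append(m)
            else:
                clusters.append(_close_cluster(current, geno, c))
                current = [m]
        clusters.append(_close_cluster(current, geno, c))
    return clusters


def _close_cluster(members: list[str], geno: GenotypeTable, chrom: int) -> dict:
    completeness = geno.calls[members].notna().sum()
    rep = completeness.idxmax()  # first maximum = leftmost on ties
    return {"representative": rep, "members": list(members), "chrom": int(chrom)}


def call_qtl(
    q_values: pd.Series | Sequence[float],
    gmap: GeneticMap,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Merge runs of consecutive markers with q < alpha into QTL intervals.

    ``q_values`` align with the map's marker order (or are indexed by marker
    name).  Returns columns chromosome, start_cM, end_cM, peak_marker,
    peak_q; a single significant marker yields a zero-width interval.
    """
    if isinstance(q_values, pd.Series):
        q = q_values.reindex(gmap.markers).to_numpy(dtype=float)
    else:
        q = np.asarray(list(q_values), dtype=float)
        if q.size != gmap.n_markers:
            raise InvalidArgumentError("q_values must align with the map")
    sig = np.where(np.isnan(q), False, q < fdr_alpha)
    chrom = gmap.table["chrom"].to_numpy()
    pos = gmap.table["pos_cM"].to_numpy()
    names = gmap.table["marker"].to_numpy()
    intervals = []
    i = 0
    n = len(q)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and chrom[j + 1] == chrom[i]:
            j += 1
        seg = slice(i, j + 1)
        peak = i + int(np.nanargmin(q[seg]))
        intervals.append(
            {
                "chromosome": int(chrom[i]),
                "start_cM": float(pos[i]),
                "end_cM": float(pos[j]),
                "peak_marker": str(names[peak]),
                "peak_q": float(q[peak]),
            }
        )
        i = j + 1
    return pd.DataFrame(intervals, columns=["chromosome", "start_cM", "end_cM", "peak_marker", "peak_q"])
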