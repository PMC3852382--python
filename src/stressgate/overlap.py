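"""Permutation test for chance colocalization of two sets of QTL intervals.

The observed statistic is the number of intervals in set A that overlap at
least one interval in set B (closed intervals, cM coordinates).  The null
re-places each A interval, with its length preserved, uniformly at random
on the genetic map: a chromosome is drawn with probability proportional to
its length among chromosomes long enough to hold the interval, then the
start position uniformly over the valid range.  The Monte-Carlo P value is
(1 + #{permutations with statistic >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneticMap, InvalidArgumentError

__all__ = ["IntervalSet", "overlap_count", "overlap_probability"]


class IntervalSet:
    """List of (chromosome, start_cM, end_cM) closed intervals within a map."""

    def __init__(self, intervals: Sequence[tuple[int, float, float]]):
        rows = []
        for chrom, start, end in intervals:
            if end < start:
                raise InvalidArgumentError(f"interval end < start on chromosome {chrom}")
            rows.append((int(chrom), float(start), float(end)))
        if not rows:
            raise InvalidArgumentError("interval set must be nonempty")
        self.table = pd.DataFrame(rows, columns=["chromosome", "start_cM", "end_cM"])

    def __len__(self) -> int:
        return len(self.table)

    def validate_against(self, gmap: GeneticMap) -> None:
        lengths = gmap.chrom_lengths()
        for _, row in self.table.iterrows():
            c = row["chromosome"]
            if c not in lengths.index:
                raise InvalidArgumentError(f"chromosome {c} not in map")
            if row["start_cM"] < 0 or row["end_cM"] > lengths.loc[c]:
                raise InvalidArgumentError(
                    f"interval ({c}, {row['start_cM']}, {row['end_cM']}) exceeds "
                    f"chromosome length {lengths.loc[c]}"
                )


def overlap_count(a: IntervalSet | pd.DataFrame, b: IntervalSet | pd.DataFrame) -> int:
    """Number of A intervals overlapping >= 1 B interval (closed endpoints)."""
    ta = a.table if isinstance(a, IntervalSet) else a
    tb = b.table if isinstance(b, IntervalSet) else b
    n = 0
    for _, ra in ta.iterrows():
        hit = (
            (tb["chromosome"] == ra["chromosome"])
            & (tb["start_cM"] <= ra["end_cM"])
            & (tb["end_cM"] >= ra["start_cM"])
        ).any()
        n += int(hit)
    return n


def overlap_probability(
    a: IntervalSet,
    b: IntervalSet,
    gmap: GeneticMap,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> float:
    """Monte-Carlo probability that >= the observed number of A intervals
    overlap B under uniform re-placement of A's intervals on the map."""
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    a.validate_against(gmap)
    b.validate_against(gmap)
    rng = np.random.default_rng(seed)
    lengths = gmap.chrom_lengths()
    chroms = lengths.index.to_numpy()
    clen = lengths.to_numpy(dtype=float)
    observed = overlap_count(a, b)
    a_lengths = (a.table["end_cM"] - a.table["start_cM"]).to_numpy()
    b_chrom = b.table["chromosome"].to_numpy()
    b_start = b.table["start_cM"].to_numpy()
    b_end = b.table["end_cM"].to_numpy()
    # Vectorized placements: (n_perm, |A|) chromosomes and starts.
    hits = np.zeros(n_perm, dtype=int)
    for j, L in enumerate(a_lengths):
        fits = clen >= L
        if not fits.any():
            raise InvalidArgumentError(f"interval of length {L} cM fits on no chromosome")
        w = np.where(fits, clen, 0.0)
        ci = rng.choice(len(chroms), size=n_perm, p=w / w.sum())
        span = clen[ci] - L
        start = rng.uniform(0.0, 1.0, size=n_perm) * span
        end = start + L
        hit = (
            (b_chrom[None, :] == chroms[ci][:, None])
            & (b_start[None, :] <= end[:, None])
            & (b_end[None, :] >= start[:, None])
        ).any(axis=1)
        hits += hit.astype(int)
    count_ge = int((hits >= observed).sum())
    return (1 + count_ge) / (n_perm + 1)
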