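"""Synthetic genetic maps, RIL/NAM genotypes, and gate-structured phenotypes.

The generator emulates (i) an intermated biparental recombinant-inbred (RIL)
population in the style of the maize IBM panel and (ii) a NAM-like design of
several RIL families sharing a common parent, plus phenotypes observed in a
factorial two-stress greenhouse design (control, drought, UV, combined) with
replicate blocks.

Meiosis uses the Haldane map function (no crossover interference): the
recombination fraction over d cM is r = (1 - exp(-2d/100))/2, and crossovers
in adjacent intervals are independent.  Line construction is explicit:
F1 hybrids, optional random intermating generations, then single-seed-descent
selfing with residual heterozygosity resolved by transmitting a single final
gamete (a linkage-respecting fair coin at each remaining heterozygous locus).
For
a selfed RIL without intermating the expected recombinant line fraction
between two markers approaches the Haldane-Waddington limit 2r/(1+2r).

Allele effects throughout are *half-differences*: the deviation of the
allele-A class mean from the population mean, so the A-vs-B class difference
is twice the effect.  This matches the reporting convention in which effects
are given relative to the population mean; beware that other tools quote the
full class difference.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ENVIRONMENTS,
    GeneticMap,
    GenotypeTable,
    InvalidArgumentError,
    PhenotypeTable,
    QTLSpec,
    TrueArchitecture,
)

__all__ = [
    "make_map",
    "simulate_ril_genotypes",
    "simulate_nam_genotypes",
    "simulate_phenotypes",
    "effects_for_variance_target",
    "place_random_qtl",
]


def make_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chrom_length: float,
    seed: Optional[int] = None,
    spacing: str = "even",
) -> GeneticMap:
    """Build a marker map with even or uniform-at-random spacing.

    Bin labels are chromosome.position-decile strings (e.g. ``3.07`` is the
    8th decile of chromosome 3), a lightweight stand-in for the maize
    community's chromosome-bin nomenclature.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise InvalidArgumentError("counts must be >= 1")
    if chrom_length <= 0:
        raise InvalidArgumentError("chromosome length must be > 0")
    if spacing not in ("even", "random"):
        raise InvalidArgumentError(f"spacing must be 'even' or 'random', got {spacing!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        m = markers_per_chromosome
        if spacing == "even":
            pos = np.linspace(0.0, chrom_length, m) if m > 1 else np.array([0.0])
        else:
            pos = np.sort(rng.uniform(0.0, chrom_length, size=m))
        for j, p in enumerate(pos):
            decile = min(int(10 * p / chrom_length), 9)
            rows.append((f"m{c:02d}_{j + 1:04d}", c, float(p), f"{c}.{decile:02d}"))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM", "bin"]))


def _gametes(h0: np.ndarray, h1: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from its two haplotypes.

    ``h0``/``h1``: (n, M) arrays of 0/1 parental-origin alleles; ``r``:
    (M-1,) switch probabilities between adjacent markers (0.5 across
    chromosome boundaries).
    """
    n, M = h0.shape
    start = rng.integers(0, 2, size=(n, 1), dtype=np.int64)
    if M > 1:
        switches = rng.random((n, M - 1)) < r
        state = (start + np.cumsum(switches, axis=1)) % 2
        state = np.concatenate([start, state], axis=1)
    else:
        state = start
    return np.where(state == 0, h0, h1)


def _ril_haplotypes(
    gmap: GeneticMap,
    n_lines: int,
    n_intermating_generations: int,
    n_selfing_generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate inbred genomes; returns (n_lines, M) 0/1 allele matrix."""
    M = gmap.n_markers
    if M == 0:
        raise InvalidArgumentError("empty genetic map")
    r = gmap.adjacent_recombination_fractions()
    # F1: every individual heterozygous at every marker.
    h0 = np.zeros((n_lines, M), dtype=np.int64)
    h1 = np.ones((n_lines, M), dtype=np.int64)
    for _ in range(n_intermating_generations):
        ma = rng.integers(0, n_lines, size=n_lines)
        pa = rng.integers(0, n_lines - 1, size=n_lines) if n_lines > 1 else np.zeros(n_lines, dtype=int)
        pa = np.where(pa >= ma, pa + 1, pa) if n_lines > 1 else pa
        g1 = _gametes(h0[ma], h1[ma], r, rng)
        g2 = _gametes(h0[pa], h1[pa], r, rng)
        h0, h1 = g1, g2
    for _ in range(n_selfing_generations):
        g1 = _gametes(h0, h1, r, rng)
        g2 = _gametes(h0, h1, r, rng)
        h0, h1 = g1, g2
    # Resolve residual heterozygosity by transmitting one final gamete: at
    # homozygous loci the gamete equals the genotype, and at the rare
    # still-heterozygous loci the choice is a fair coin that respects
    # linkage (zero-distance loci resolve together).
    return _gametes(h0, h1, r, rng)


def simulate_ril_genotypes(
    gmap: GeneticMap,
    n_lines: int,
    n_intermating_generations: int = 0,
    seed: Optional[int] = None,
    n_selfing_generations: int = 5,
    missing_fraction: float = 0.0,
    family_label: str = "fam01",
    line_prefix: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeTable:
    """Simulate a biparental RIL population.

    ``n_intermating_generations`` random-mating generations are inserted
    between the F1 and selfing, as in intermated populations; selfing runs
    for ``n_selfing_generations`` with residual heterozygosity resolved by a
    fair coin per locus.
    """
    if n_lines < 1:
        raise InvalidArgumentError("n_lines must be >= 1")
    if n_intermating_generations < 0:
        raise InvalidArgumentError("n_intermating_generations must be >= 0")
    if not 0.0 <= missing_fraction < 1.0:
        raise InvalidArgumentError("missing_fraction must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    alleles = _ril_haplotypes(gmap, n_lines, n_intermating_generations, n_selfing_generations, rng)
    codes = np.where(alleles == 0, "A", "B").astype(object)
    if missing_fraction > 0:
        mask = rng.random(codes.shape) < missing_fraction
        codes[mask] = np.nan
    prefix = line_prefix if line_prefix is not None else family_label
    ids = [f"{prefix}_L{i + 1:04d}" for i in range(n_lines)]
    calls = pd.DataFrame(codes, index=pd.Index(ids, name="line_id"), columns=gmap.markers)
    family = pd.Series(family_label, index=calls.index, name="family")
    return GenotypeTable(calls=calls, family=family)


def simulate_nam_genotypes(
    gmap: GeneticMap,
    n_families: int,
    lines_per_family: int,
    seed: Optional[int] = None,
    family_labels: Optional[Sequence[str]] = None,
    missing_fraction: float = 0.0,
) -> GenotypeTable:
    """Simulate a NAM-like design: families of RILs sharing common parent A.

    Each family behaves exactly like :func:`simulate_ril_genotypes` without
    intermating; allele A denotes the shared (reference) parent in every
    family, allele B the family-specific parent.
    """
    if n_families < 1 or lines_per_family < 1:
        raise InvalidArgumentError("counts must be >= 1")
    if family_labels is None:
        family_labels = [f"fam{k + 1:02d}" for k in range(n_families)]
    if len(family_labels) != n_families:
        raise InvalidArgumentError("need one label per family")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_families)
    parts = []
    for label, ss in zip(family_labels, children):
        rng = np.random.default_rng(ss)
        parts.append(
            simulate_ril_genotypes(
                gmap,
                lines_per_family,
                n_intermating_generations=0,
                rng=rng,
                missing_fraction=missing_fraction,
                family_label=label,
            )
        )
    calls = pd.concat([p.calls for p in parts])
    family = pd.concat([p.family for p in parts])
    return GenotypeTable(calls=calls, family=family)


def simulate_phenotypes(
    geno: GenotypeTable,
    arch: TrueArchitecture,
    n_blocks: int = 4,
    seed: Optional[int] = None,
    trait: str = "trait",
) -> PhenotypeTable:
    """Simulate the factorial two-stress experiment.

    value = trait_mean + block(b, env) + sum_q s(line, q) * e(q, env) + noise,
    with s = +1 for allele A and -1 for allele B, and e(q, env) following the
    QTL's gate rule (all gates give e(control) = 0).  Block effects are drawn
    once per (block, environment) cell from N(0, block_sd^2), emulating
    month-replicates crossed with treatments.  A missing genotype at any QTL
    marker makes that line's phenotypes missing (never silently imputed).
    """
    if n_blocks < 1:
        raise InvalidArgumentError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    for q in arch.qtl:
        if q.marker not in geno.marker_names:
            raise InvalidArgumentError(f"architecture marker {q.marker!r} not in genotype table")
    n = geno.n_lines
    signs = geno.signs()
    # genetic value per line x environment
    g = np.zeros((n, len(ENVIRONMENTS)))
    for q in arch.qtl:
        e = q.env_effects()
        s = signs[q.marker].to_numpy()
        for j, env in enumerate(ENVIRONMENTS):
            g[:, j] += s * e[env]
    block_eff = rng.normal(0.0, arch.block_sd, size=(len(ENVIRONMENTS), n_blocks))
    frames = []
    line_ids = geno.line_ids.to_numpy()
    fams = geno.family.to_numpy()
    for j, env in enumerate(ENVIRONMENTS):
        for b in range(n_blocks):
            noise = rng.normal(0.0, arch.residual_sd, size=n) if arch.residual_sd > 0 else np.zeros(n)
            values = arch.trait_mean + block_eff[j, b] + g[:, j] + noise
            frames.append(
                pd.DataFrame(
                    {
                        "line_id": line_ids,
                        "family": fams,
                        "environment": env,
                        "block": b + 1,
                        "trait": trait,
                        "value": values,
                    }
                )
            )
    return PhenotypeTable(pd.concat(frames, ignore_index=True))


def effects_for_variance_target(
    target_r2: Sequence[float],
    residual_sd: float,
    mode: str = "joint",
) -> np.ndarray:
    """Half-difference effect sizes hitting per-QTL variance-explained targets.

    With allele frequency 0.5 and +/-1 coding, a QTL of half-difference a
    contributes genetic variance a^2.  Two target conventions are supported:

    - ``joint``: a_i^2 / (sum_j a_j^2 + residual_sd^2) = t_i, i.e. targets
      are fractions of the total phenotypic variance with all QTL
      segregating; requires sum(t) < 1.
    - ``marginal``: a_i^2 / (a_i^2 + residual_sd^2) = t_i, i.e. each QTL's
      share against the residual alone (the usual reading of "a QTL of
      effect size 50%" when the stated sizes sum past 100%).
    """
    t = np.asarray(list(target_r2), dtype=float)
    if ((t < 0) | (t >= 1)).any():
        raise InvalidArgumentError("each variance target must be in [0, 1)")
    if residual_sd <= 0:
        raise InvalidArgumentError("residual_sd must be > 0")
    if mode == "joint":
        total = t.sum()
        if total >= 1:
            raise InvalidArgumentError(
                f"joint variance targets sum to {total:.3f} >= 1; infeasible"
            )
        v_total = residual_sd**2 / (1.0 - total)
        return np.sqrt(t * v_total)
    if mode == "marginal":
        return residual_sd * np.sqrt(t / (1.0 - t))
    raise InvalidArgumentError(f"mode must be 'joint' or 'marginal', got {mode!r}")


def place_random_qtl(
    gmap: GeneticMap,
    r2_targets: Sequence[float],
    residual_sd: float,
    rng: np.random.Generator,
    gate: str = "independent",
    mode: str = "marginal",
    trait_mean: float = 10.0,
    block_sd: float = 0.5,
) -> TrueArchitecture:
    """Place QTL at distinct random markers with given variance targets.

    Used by the stepwise-calibration study: each QTL gets equal UV and
    drought inputs of the computed half-difference (for the AND gate the
    effect is placed in the combined environment).
    """
    k = len(list(r2_targets))
    if k > gmap.n_markers:
        raise InvalidArgumentError("more QTL than markers")
    effects = effects_for_variance_target(r2_targets, residual_sd, mode=mode)
    idx = rng.choice(gmap.n_markers, size=k, replace=False)
    qtl = []
    for a, i in zip(effects, idx):
        marker = gmap.table.loc[i, "marker"]
        if gate == "AND_gate":
            qtl.append(QTLSpec(marker=marker, gate=gate, effect_combined=float(a)))
        elif gate == "XOR":
            qtl.append(QTLSpec(marker=marker, gate=gate, effect_uv=float(a), effect_drought=-float(a)))
        else:
            qtl.append(QTLSpec(marker=marker, gate=gate, effect_uv=float(a), effect_drought=float(a)))
    return TrueArchitecture(
        qtl=tuple(qtl), trait_mean=trait_mean, block_sd=block_sd, residual_sd=residual_sd
    )
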