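"""Core data containers for the two-stress QTL pipeline.

All tabular containers wrap :class:`pandas.DataFrame` objects and validate
their schema on construction.  The genetic coordinate system is continuous
centimorgans (cM), 0-based at the start of each chromosome; intervals are
closed.  Allele codes are ``A`` (the common/reference parent, e.g. B73) and
``B`` (the alternate parent); inbred lines carry exactly one code per marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of treatment environments.  ``combined`` means both
#: stresses (drought and UV) applied together.
ENVIRONMENTS: tuple[str, ...] = ("control", "drought", "UV", "combined")

#: Gate labels understood by the phenotype simulator.  A gate is the logical
#: rule by which the two stress inputs combine into a locus's
#: environment-specific allele effect.
GATES: tuple[str, ...] = (
    "independent",
    "AND_gate",
    "OR_gate",
    "XOR",
    "attenuator_UV",
    "attenuator_drought",
)

ALLELE_CODES = ("A", "B")


class StressgateError(Exception):
    """Base class for errors raised by this package."""


class InvalidArgumentError(StressgateError, ValueError):
    """A function argument violates its contract."""


class InsufficientDataError(StressgateError, ValueError):
    """The data do not support the requested estimate."""


class ParseError(StressgateError, ValueError):
    """A file violates its schema; the message names the offending line."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: columns ``marker``, ``chrom``, ``pos_cM``, ``bin``.

    Invariants: positions nondecreasing within chromosome, marker names
    unique, every chromosome nonempty.  Rows are sorted by (chrom, pos_cM)
    on construction and indexed 0..n-1.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker", "chrom", "pos_cM", "bin"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise InvalidArgumentError(f"map table missing columns {missing}")
        tab = self.table[required].copy()
        tab["chrom"] = tab["chrom"].astype(int)
        tab["pos_cM"] = tab["pos_cM"].astype(float)
        if (tab["chrom"] < 1).any():
            raise InvalidArgumentError("chromosome numbers must be >= 1")
        if (tab["pos_cM"] < 0).any():
            raise InvalidArgumentError("cM positions must be >= 0")
        if tab["marker"].duplicated().any():
            dup = tab.loc[tab["marker"].duplicated(), "marker"].iloc[0]
            raise InvalidArgumentError(f"duplicate marker name {dup!r}")
        tab = tab.sort_values(["chrom", "pos_cM"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "table", tab)

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.table["chrom"].to_numpy())

    def chrom_lengths(self) -> pd.Series:
        """Chromosome length = position of the last marker (0-based start)."""
        return self.table.groupby("chrom")["pos_cM"].max()

    def positions_of(self, markers: Sequence[str]) -> pd.DataFrame:
        idx = self.table.set_index("marker")
        try:
            return idx.loc[list(markers)]
        except KeyError as exc:
            raise InvalidArgumentError(f"marker not in map: {exc.args[0]}") from exc

    def adjacent_recombination_fractions(self) -> np.ndarray:
        """Haldane recombination fraction between consecutive markers.

        Returns an array of length n_markers - 1; entries that straddle a
        chromosome boundary are 0.5 (unlinked).
        """
        pos = self.table["pos_cM"].to_numpy()
        chrom = self.table["chrom"].to_numpy()
        d = np.diff(pos)
        r = haldane_r(d)
        r[np.diff(chrom) != 0] = 0.5
        return r


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Map distance (cM) -> recombination fraction, Haldane (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass(frozen=True)
class GenotypeTable:
    """Lines x markers allele calls plus a family label per line.

    ``calls`` is a DataFrame indexed by line_id with one column per marker,
    values in {"A", "B"} or NaN for missing.  ``family`` is a Series indexed
    identically.  A biparental population has a single family label.
    """

    calls: pd.DataFrame
    family: pd.Series

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.family.index):
            raise InvalidArgumentError("genotype calls and family labels disagree on line ids")
        if self.calls.index.duplicated().any():
            raise InvalidArgumentError("duplicate line ids")
        vals = self.calls.to_numpy(dtype=object)
        ok = np.isin(vals, ALLELE_CODES) | pd.isna(vals.astype(object))
        if not ok.all():
            bad = vals[~ok].flat[0]
            raise InvalidArgumentError(f"unknown allele code {bad!r}")

    @property
    def line_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def marker_names(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_lines(self) -> int:
        return len(self.calls)

    @property
    def families(self) -> np.ndarray:
        return np.unique(self.family.to_numpy())

    def signs(self) -> pd.DataFrame:
        """Numeric coding: +1 for allele A, -1 for B, NaN for missing."""
        return self.calls.apply(lambda c: c.map({"A": 1.0, "B": -1.0}))

    def allele_frequency(self, allele: str = "B") -> pd.Series:
        """Per-marker frequency of ``allele`` among non-missing calls."""
        return (self.calls == allele).sum() / self.calls.notna().sum()


@dataclass(frozen=True)
class QTLSpec:
    """One ground-truth locus: a marker, its gate, and per-stress effects.

    Effects are half-differences: the deviation of the allele-A class mean
    from the population mean, in trait units (so the A-vs-B class difference
    is twice the effect).  ``effect_combined`` is derived from the gate rule
    when None; only the AND gate requires it explicitly.
    """

    marker: str
    gate: str
    effect_uv: float = 0.0
    effect_drought: float = 0.0
    effect_combined: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gate not in GATES:
            raise InvalidArgumentError(f"unknown gate {self.gate!r}; expected one of {GATES}")
        if self.gate == "AND_gate" and self.effect_combined is None:
            raise InvalidArgumentError("AND_gate requires an explicit effect_combined")
        if self.gate == "XOR" and self.effect_drought not in (0.0, -self.effect_uv):
            raise InvalidArgumentError("XOR forces effect_drought = -effect_uv")

    def env_effects(self) -> dict[str, float]:
        """Per-environment allele-A effect implied by the gate rule."""
        euv, edr = self.effect_uv, self.effect_drought
        if self.gate in ("independent", "OR_gate"):
            comb = self.effect_combined if self.effect_combined is not None else euv + edr
            return {"control": 0.0, "UV": euv, "drought": edr, "combined": comb}
        if self.gate == "AND_gate":
            return {"control": 0.0, "UV": 0.0, "drought": 0.0, "combined": float(self.effect_combined)}
        if self.gate == "XOR":
            return {"control": 0.0, "UV": euv, "drought": -euv, "combined": 0.0}
        if self.gate == "attenuator_UV":
            return {"control": 0.0, "UV": euv, "drought": 0.0, "combined": 0.0}
        if self.gate == "attenuator_drought":
            return {"control": 0.0, "UV": 0.0, "drought": edr, "combined": 0.0}
        raise InvalidArgumentError(f"unknown gate {self.gate!r}")


@dataclass(frozen=True)
class TrueArchitecture:
    """Ground-truth genetic architecture for the phenotype simulator."""

    qtl: tuple[QTLSpec, ...]
    trait_mean: float = 10.0
    block_sd: float = 0.5
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.block_sd < 0 or self.residual_sd < 0:
            raise InvalidArgumentError("standard deviations must be >= 0")
        object.__setattr__(self, "qtl", tuple(self.qtl))

    def to_dict(self) -> dict:
        return {
            "trait_mean": self.trait_mean,
            "block_sd": self.block_sd,
            "residual_sd": self.residual_sd,
            "qtl": [
                {
                    "marker": q.marker,
                    "gate": q.gate,
                    "effect_uv": q.effect_uv,
                    "effect_drought": q.effect_drought,
                    "effect_combined": q.effect_combined,
                }
                for q in self.qtl
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrueArchitecture":
        return cls(
            qtl=tuple(
                QTLSpec(
                    marker=q["marker"],
                    gate=q["gate"],
                    effect_uv=float(q.get("effect_uv", 0.0)),
                    effect_drought=float(q.get("effect_drought", 0.0)),
                    effect_combined=(None if q.get("effect_combined") is None else float(q["effect_combined"])),
                )
                for q in d["qtl"]
            ),
            trait_mean=float(d.get("trait_mean", 10.0)),
            block_sd=float(d.get("block_sd", 0.5)),
            residual_sd=float(d.get("residual_sd", 1.0)),
        )


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format phenotype records.

    Columns: line_id, family, environment, block, trait, value.  The key
    (line_id, environment, block, trait) is unique; environments come from
    the closed vocabulary.
    """

    data: pd.DataFrame

    REQUIRED = ("line_id", "family", "environment", "block", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InvalidArgumentError(f"phenotype table missing columns {missing}")
        dat = self.data[list(self.REQUIRED)].copy()
        bad_env = set(dat["environment"].unique()) - set(ENVIRONMENTS)
        if bad_env:
            raise InvalidArgumentError(
                f"unknown environment label(s) {sorted(bad_env)}; allowed: {ENVIRONMENTS}"
            )
        dat["block"] = dat["block"].astype(int)
        if (dat["block"] < 1).any():
            raise InvalidArgumentError("block numbers must be >= 1")
        dat["value"] = dat["value"].astype(float)
        key = ["line_id", "environment", "block", "trait"]
        if dat.duplicated(subset=key).any():
            row = dat[dat.duplicated(subset=key)].iloc[0]
            raise InvalidArgumentError(
                "duplicate phenotype record for "
                f"({row['line_id']}, {row['environment']}, {row['block']}, {row['trait']})"
            )
        object.__setattr__(self, "data", dat.reset_index(drop=True))

    @property
    def traits(self) -> np.ndarray:
        return np.unique(self.data["trait"].to_numpy())

    @property
    def environments(self) -> np.ndarray:
        return np.unique(self.data["environment"].to_numpy())

    def subset(self, trait: str, environment: Optional[str] = None) -> pd.DataFrame:
        if trait not in self.traits:
            raise InvalidArgumentError(f"trait {trait!r} not present (have {list(self.traits)})")
        d = self.data[self.data["trait"] == trait]
        if environment is not None:
            if environment not in ENVIRONMENTS:
                raise InvalidArgumentError(f"unknown environment {environment!r}")
            d = d[d["environment"] == environment]
        return d.dropna(subset=["value"]).reset_index(drop=True)
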