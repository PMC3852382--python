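"""Readers and writers for the pipeline's tab-separated file schemas.

All files are UTF-8 TSV with '.' decimal separator and ``NA`` for missing
values; lines starting with ``#`` are header comments (tool version and
configuration hash) and are skipped on read.  Schema violations are
reported with the 1-based line number of the offending record.

Schemas:

- map TSV: columns ``marker  chrom  pos_cM  bin``.
- genotype TSV: ``line_id  family  <marker1> <marker2> ...`` with allele
  codes A/B/NA.
- phenotype TSV: ``line_id  family  environment  block  trait  value``.
- truth JSON: serialized ground-truth architecture.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    ALLELE_CODES,
    ENVIRONMENTS,
    GeneticMap,
    GenotypeTable,
    ParseError,
    PhenotypeTable,
    TrueArchitecture,
)

__all__ = [
    "read_map", "write_map",
    "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_phenotypes",
    "read_truth", "write_truth",
    "config_hash",
]

_NA = "NA"


def config_hash(config: object) -> str:
    """Short stable hash of a configuration mapping, for output provenance."""
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _header_lines(cfg_hash: Optional[str]) -> str:
    h = f" config={cfg_hash}" if cfg_hash else ""
    return f"# stressgate v{__version__}{h}\n"


def _read_tsv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a TSV skipping comment lines; returns (frame, source line numbers)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    keep = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if not keep:
        raise ParseError(f"{path}: no records")
    header = keep[0][1].rstrip("\n").split("\t")
    rows = []
    lineno = []
    for no, ln in keep[1:]:
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ParseError(f"{path}:{no}: expected {len(header)} fields, got {len(fields)}")
        rows.append(fields)
        lineno.append(no)
    df = pd.DataFrame(rows, columns=header)
    return df, np.asarray(lineno)


def write_map(gmap: GeneticMap, path: str | Path, cfg_hash: Optional[str] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(cfg_hash))
        gmap.table.to_csv(fh, sep="\t", index=False)


def read_map(path: str | Path) -> GeneticMap:
    df, lineno = _read_tsv(path)
    for col in ("marker", "chrom", "pos_cM", "bin"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    for col, caster in (("chrom", int), ("pos_cM", float)):
        try:
            df[col] = df[col].map(caster)
        except ValueError:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"{path}:{lineno[bad.index[0]]}: non-numeric {col} value {bad.iloc[0]!r}"
            ) from None
    return GeneticMap(df)


def write_genotypes(geno: GenotypeTable, path: str | Path, cfg_hash: Optional[str] = None) -> None:
    out = geno.calls.copy()
    out.insert(0, "family", geno.family)
    out.index.name = "line_id"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(cfg_hash))
        out.to_csv(fh, sep="\t", na_rep=_NA)


def read_genotypes(path: str | Path) -> GenotypeTable:
    df, lineno = _read_tsv(path)
    if df.columns[0] != "line_id" or df.columns[1] != "family":
        raise ParseError(f"{path}: first two columns must be line_id and family")
    markers = list(df.columns[2:])
    if not markers:
        raise ParseError(f"{path}: no marker columns")
    calls = df[markers].copy()
    vals = calls.to_numpy(dtype=object)
    ok = np.isin(vals, list(ALLELE_CODES) + [_NA])
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ParseError(
            f"{path}:{lineno[i]}: unknown allele code {vals[i, j]!r} at marker {markers[j]}"
        )
    calls = calls.replace(_NA, np.nan)
    calls.columns = pd.Index(markers, name="marker")
    calls.index = pd.Index(df["line_id"], name="line_id")
    family = pd.Series(df["family"].to_numpy(), index=calls.index, name="family")
    return GenotypeTable(calls=calls, family=family)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path, cfg_hash: Optional[str] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(cfg_hash))
        pheno.data.to_csv(fh, sep="\t", index=False, na_rep=_NA)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df, lineno = _read_tsv(path)
    for col in PhenotypeTable.REQUIRED:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad_env = ~df["environment"].isin(ENVIRONMENTS)
    if bad_env.any():
        i = int(np.flatnonzero(bad_env)[0])
        raise ParseError(
            f"{path}:{lineno[i]}: unknown environment {df['environment'].iloc[i]!r} "
            f"(allowed: {', '.join(ENVIRONMENTS)})"
        )
    try:
        df["block"] = df["block"].map(int)
    except ValueError:
        bad = pd.to_numeric(df["block"], errors="coerce").isna()
        i = int(np.flatnonzero(bad)[0])
        raise ParseError(f"{path}:{lineno[i]}: non-integer block {df['block'].iloc[i]!r}") from None
    values = pd.to_numeric(df["value"].replace(_NA, np.nan), errors="coerce")
    bad_val = values.isna() & (df["value"] != _NA)
    if bad_val.any():
        i = int(np.flatnonzero(bad_val)[0])
        raise ParseError(f"{path}:{lineno[i]}: non-numeric value {df['value'].iloc[i]!r}")
    df["value"] = values
    key = ["line_id", "environment", "block", "trait"]
    dups = df.duplicated(subset=key)
    if dups.any():
        i = int(np.flatnonzero(dups)[0])
        raise ParseError(f"{path}:{lineno[i]}: duplicate (line, environment, block, trait) record")
    return PhenotypeTable(df)


def write_truth(arch: TrueArchitecture, path: str | Path, cfg_hash: Optional[str] = None) -> None:
    doc = arch.to_dict()
    doc["_tool"] = f"stressgate v{__version__}"
    if cfg_hash:
        doc["_config"] = cfg_hash
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_truth(path: str | Path) -> TrueArchitecture:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return TrueArchitecture.from_dict(doc)
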