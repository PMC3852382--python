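"""Configuration and the umbrella pipeline: simulate -> scan -> smooth -> classify.

All randomness flows from the single root seed in the configuration; no
stage consults wall-clock or global state, so a configuration reproduces
its outputs byte-for-byte.  Every output file carries a header comment with
the tool version and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import io
from .datatypes import (
    GATES,
    GeneticMap,
    GenotypeTable,
    InvalidArgumentError,
    PhenotypeTable,
    QTLSpec,
    TrueArchitecture,
)
from .gates import architecture_fit_report
from .scan import allele_effects, scan_interaction
from .simulate import (
    effects_for_variance_target,
    make_map,
    simulate_nam_genotypes,
    simulate_phenotypes,
    simulate_ril_genotypes,
)
from .smooth import SmoothingConfig, add_smoothing, call_qtl
from .stepwise import StepwiseConfig, joint_stepwise

__all__ = ["PipelineConfig", "SimulateConfig", "run_pipeline", "demo_config"]

log = logging.getLogger("stressgate")


def _check_keys(d: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise InvalidArgumentError(f"unknown configuration key(s) in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class SimulateConfig:
    """Parameters of the optional simulation stage."""

    design: str = "ibm"  # "ibm" (intermated biparental) or "nam"
    n_lines: int = 92
    families: int = 5
    lines_per_family: int = 50
    n_chromosomes: int = 10
    markers_per_chromosome: int = 15
    chrom_length: float = 150.0
    intermating_generations: int = 4
    blocks: int = 4
    trait: str = "trait"
    gates: tuple[str, ...] = GATES
    r2: float = 0.2
    trait_mean: float = 10.0
    block_sd: float = 0.5
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.design not in ("ibm", "nam"):
            raise InvalidArgumentError("design must be 'ibm' or 'nam'")
        for g in self.gates:
            if g not in GATES:
                raise InvalidArgumentError(f"unknown gate {g!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulateConfig":
        _check_keys(d, {f.name for f in dataclasses.fields(cls)}, "simulate")
        d = dict(d)
        if "gates" in d:
            d["gates"] = tuple(d["gates"])
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline-level configuration; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "stressgate_out"
    simulate: Optional[SimulateConfig] = None
    map_path: Optional[str] = None
    geno_path: Optional[str] = None
    pheno_path: Optional[str] = None
    truth_path: Optional[str] = None
    trait: str = "trait"
    smooth: SmoothingConfig = field(default_factory=SmoothingConfig)
    stepwise: Optional[StepwiseConfig] = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        allowed = {
            "seed", "outdir", "simulate", "paths", "trait", "smooth", "stepwise",
        }
        _check_keys(d, allowed, "config")
        kw: dict = {"seed": int(d.get("seed", 0)), "outdir": str(d.get("outdir", "stressgate_out"))}
        if "trait" in d:
            kw["trait"] = str(d["trait"])
        if d.get("simulate") is not None:
            kw["simulate"] = SimulateConfig.from_dict(d["simulate"])
        paths = d.get("paths") or {}
        _check_keys(paths, {"map", "geno", "pheno", "truth"}, "paths")
        kw["map_path"] = paths.get("map")
        kw["geno_path"] = paths.get("geno")
        kw["pheno_path"] = paths.get("pheno")
        kw["truth_path"] = paths.get("truth")
        if d.get("smooth") is not None:
            _check_keys(
                d["smooth"],
                {"window", "method", "fdr_alpha", "cluster_r2", "rank_transform"},
                "smooth",
            )
            kw["smooth"] = SmoothingConfig(**d["smooth"])
        if d.get("stepwise") is not None:
            _check_keys(d["stepwise"], {"sle", "max_terms", "tp_window"}, "stepwise")
            kw["stepwise"] = StepwiseConfig(**d["stepwise"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc or {})

    def to_dict(self) -> dict:
        doc: dict = {"seed": self.seed, "outdir": self.outdir, "trait": self.trait}
        if self.simulate is not None:
            doc["simulate"] = dataclasses.asdict(self.simulate)
        doc["paths"] = {
            "map": self.map_path, "geno": self.geno_path,
            "pheno": self.pheno_path, "truth": self.truth_path,
        }
        doc["smooth"] = dataclasses.asdict(self.smooth)
        if self.stepwise is not None:
            doc["stepwise"] = dataclasses.asdict(self.stepwise)
        return doc


def _simulate_stage(cfg: PipelineConfig, outdir: Path, cfg_hash: str):
    sim = cfg.simulate
    ss = np.random.SeedSequence(cfg.seed)
    map_ss, geno_ss, pheno_ss = ss.spawn(3)
    gmap = make_map(
        sim.n_chromosomes, sim.markers_per_chromosome, sim.chrom_length,
        seed=int(map_ss.generate_state(1)[0] % (2**31)),
    )
    if sim.design == "ibm":
        geno = simulate_ril_genotypes(
            gmap, sim.n_lines, sim.intermating_generations,
            seed=int(geno_ss.generate_state(1)[0] % (2**31)),
        )
    else:
        geno = simulate_nam_genotypes(gmap, sim.families, sim.lines_per_family, seed=geno_ss)
    # one QTL per requested gate, round-robin across chromosomes (middle marker)
    a = float(effects_for_variance_target([sim.r2], sim.residual_sd, mode="marginal")[0])
    qtl = []
    chroms = list(gmap.chromosomes)
    for i, gate in enumerate(sim.gates):
        c = chroms[i % len(chroms)]
        sub = gmap.table[gmap.table["chrom"] == c]
        marker = sub.iloc[len(sub) // 2]["marker"]
        if gate == "AND_gate":
            qtl.append(QTLSpec(marker=marker, gate=gate, effect_combined=a))
        elif gate == "XOR":
            qtl.append(QTLSpec(marker=marker, gate=gate, effect_uv=a, effect_drought=-a))
        elif gate in ("attenuator_UV", "independent"):
            qtl.append(QTLSpec(marker=marker, gate=gate, effect_uv=a))
        elif gate == "attenuator_drought":
            qtl.append(QTLSpec(marker=marker, gate=gate, effect_drought=a))
        else:  # OR_gate
            qtl.append(QTLSpec(marker=marker, gate=gate, effect_uv=a, effect_drought=a))
    arch = TrueArchitecture(
        qtl=tuple(qtl), trait_mean=sim.trait_mean,
        block_sd=sim.block_sd, residual_sd=sim.residual_sd,
    )
    pheno = simulate_phenotypes(
        geno, arch, n_blocks=sim.blocks,
        seed=int(pheno_ss.generate_state(1)[0] % (2**31)), trait=sim.trait,
    )
    io.write_map(gmap, outdir / "map.tsv", cfg_hash)
    io.write_genotypes(geno, outdir / "genotypes.tsv", cfg_hash)
    io.write_phenotypes(pheno, outdir / "phenotypes.tsv", cfg_hash)
    io.write_truth(arch, outdir / "truth.json", cfg_hash)
    return gmap, geno, pheno, arch


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute simulate (optional) -> scan -> smooth -> classify (-> stepwise).

    Returns a result bundle: map, genotypes, phenotypes, truth, scan result,
    called intervals, pattern calls and the fit report; writes TSV outputs
    and a log under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hash_doc = {k: v for k, v in cfg.to_dict().items() if k != "outdir"}
    cfg_hash = io.config_hash(hash_doc)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config hash %s, seed %d", cfg_hash, cfg.seed)
        if cfg.simulate is not None:
            stage = "simulate"
            gmap, geno, pheno, truth = _simulate_stage(cfg, outdir, cfg_hash)
            trait = cfg.simulate.trait
            log.info("simulate: %d lines, %d markers", geno.n_lines, gmap.n_markers)
        else:
            stage = "load"
            if not (cfg.map_path and cfg.geno_path and cfg.pheno_path):
                raise InvalidArgumentError(
                    "simulate disabled: paths.map, paths.geno and paths.pheno are required"
                )
            gmap = io.read_map(cfg.map_path)
            geno = io.read_genotypes(cfg.geno_path)
            pheno = io.read_phenotypes(cfg.pheno_path)
            truth = io.read_truth(cfg.truth_path) if cfg.truth_path else None
            trait = cfg.trait
        stage = "scan"
        scan = scan_interaction(geno, pheno, trait, gmap=gmap)
        stage = "smooth"
        scan = add_smoothing(scan, gmap, cfg.smooth)
        scan.table.pipe(_write_tsv, outdir / "scan.tsv", cfg_hash)
        intervals = call_qtl(
            pd.Series(scan.table["q_value"].to_numpy(), index=scan.table["marker"]),
            gmap, cfg.smooth.fdr_alpha,
        )
        _write_tsv(intervals, outdir / "qtl_intervals.tsv", cfg_hash)
        log.info("smooth: %d markers, %d intervals", gmap.n_markers, len(intervals))
        stage = "classify"
        calls, report = _classify_stage(geno, pheno, trait, gmap, intervals, truth)
        _write_tsv(calls, outdir / "gate_calls.tsv", cfg_hash)
        if report is not None:
            with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
                fh.write(f"# stressgate v{_version()} config={cfg_hash}\n")
                fh.write("Observed pattern counts:\n")
                fh.write(report["counts"].to_string() + "\n")
                if report["confusion"] is not None:
                    fh.write("\nExpected vs observed (truth known):\n")
                    fh.write(report["confusion"].to_string() + "\n")
        result = {
            "map": gmap, "genotypes": geno, "phenotypes": pheno, "truth": truth,
            "scan": scan, "intervals": intervals, "calls": calls, "report": report,
        }
        if cfg.stepwise is not None:
            stage = "stepwise"
            sw = joint_stepwise(geno, pheno, trait, cfg.stepwise)
            _write_tsv(sw.entries, outdir / "stepwise_terms.tsv", cfg_hash)
            eff = sw.effect_table()
            if eff is not None:
                _write_tsv(eff, outdir / "stepwise_effects.tsv", cfg_hash)
            result["stepwise"] = sw
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _classify_stage(geno, pheno, trait, gmap, intervals, truth, match_window: float = 10.0):
    """Classify interval peak markers; expected labels come from the nearest
    true QTL within ``match_window`` cM on the same chromosome."""
    from .gates import GatePatternCall, classify_locus, expected_pattern

    truth_pos = None
    if truth is not None and len(truth.qtl) > 0:
        truth_pos = gmap.positions_of([q.marker for q in truth.qtl])
    calls = []
    for _, row in intervals.iterrows():
        marker = row["peak_marker"]
        eff = allele_effects(geno, pheno, trait, marker)
        if "control" in eff.index and bool(eff.loc["control", "significant"]):
            log.info("classify: %s excluded (significant control-environment effect)", marker)
            continue
        call = classify_locus(eff, locus=marker)
        if truth_pos is not None:
            mrow = gmap.positions_of([marker]).iloc[0]
            same = truth_pos[truth_pos["chrom"] == mrow["chrom"]]
            if len(same):
                dist = (same["pos_cM"] - mrow["pos_cM"]).abs()
                if dist.min() <= match_window:
                    q = truth.qtl[[q.marker for q in truth.qtl].index(dist.idxmin())]
                    call = GatePatternCall(
                        locus=call.locus,
                        observed_label=call.observed_label,
                        evidence=call.evidence,
                        expected_label=expected_pattern(q.gate, q.effect_uv, q.effect_drought),
                    )
        calls.append(call)
    rows = [
        {"locus": c.locus, "observed": c.observed_label, "expected": c.expected_label}
        for c in calls
    ]
    calls_df = pd.DataFrame(rows, columns=["locus", "observed", "expected"])
    report = architecture_fit_report(calls, truth) if calls else None
    return calls_df, report


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# stressgate v{_version()} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _version() -> str:
    from . import __version__

    return __version__


def demo_config(outdir: str = "stressgate_demo", seed: int = 7) -> PipelineConfig:
    """Small end-to-end demonstration: one QTL per gate in an IBM-style design."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        simulate=SimulateConfig(
            design="ibm", n_lines=150, n_chromosomes=6, markers_per_chromosome=15,
            chrom_length=140.0, intermating_generations=4, blocks=4, r2=0.3,
        ),
        smooth=SmoothingConfig(window=3, method="simes", fdr_alpha=0.05),
    )
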