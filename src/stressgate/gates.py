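"""Classify per-environment allele-effect patterns into signaling-gate categories.

A locus detected in the factorial two-stress experiment shows a pattern of
significant allele effects across the drought, UV and combined treatments.
Under a simple logic-gate view of stress signaling, each generating
mechanism predicts a distinct pattern:

- separate (independent) pathways: the single-stress effect persists, with
  the same sign and size, in the combined treatment;
- an AND sensor (activated only by both stresses): an effect only in the
  combined treatment ("dose-dependent / combined-only");
- an OR integrator: effects in both single stresses and their sum in the
  combined treatment;
- an OR integrator with opposite single-stress allele effects (XOR): both
  single-stress effects significant, cancellation in the combined;
- an attenuating modifier (a constitutive sensor for one stress that
  represses the other pathway's signal): a single-stress effect that
  disappears in the combined treatment ("UV effect lost" / "drought effect
  lost").

Classification uses only significance flags and effect signs/CIs, never raw
magnitudes alone.  "Significant" means the 95% CI excludes zero.  Loci with
a significant control-environment effect are constitutive growth loci, not
stress-specific ones, and must be excluded before classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GATES, InvalidArgumentError, TrueArchitecture

__all__ = [
    "PATTERN_LABELS",
    "GatePatternCall",
    "classify_locus",
    "expected_pattern",
    "classify_scan",
    "architecture_fit_report",
]

PATTERN_LABELS = (
    "uv_effect_lost",
    "drought_effect_lost",
    "combined_only_dose_dependent",
    "additive_opposite_xor",
    "additive_or",
    "synergistic",
    "independent_consistent",
    "complex",
)

# Absolute tolerance for "equal within CI" comparisons when the CI has zero
# width (noiseless fits).
_ATOL = 1e-8


@dataclass(frozen=True)
class GatePatternCall:
    locus: str
    observed_label: str
    evidence: pd.DataFrame  # per-environment effect/se/ci/significant
    expected_label: Optional[str] = None


def _row(effects: pd.DataFrame, env: str):
    if env not in effects.index:
        raise InvalidArgumentError(f"missing environment {env!r} in effects table")
    return effects.loc[env]


def classify_locus(effects: pd.DataFrame, locus: str = "") -> GatePatternCall:
    """Assign the observed cross-environment pattern label for one locus.

    ``effects`` is indexed by environment with columns effect, se, ci_lo,
    ci_hi, significant (allele-A deviations, as from
    :func:`stressgate.scan.allele_effects`).  The control row, when present,
    must be non-significant; constitutive loci are excluded upstream.
    """
    if "control" in effects.index and bool(effects.loc["control", "significant"]):
        raise InvalidArgumentError(
            f"locus {locus or '<unnamed>'} has a significant control-environment effect; "
            "constitutive loci are excluded from gate classification"
        )
    uv, dr, cb = (_row(effects, e) for e in ("UV", "drought", "combined"))
    s_uv, s_dr, s_cb = (bool(r["significant"]) for r in (uv, dr, cb))
    e_uv, e_dr, e_cb = (float(r["effect"]) for r in (uv, dr, cb))
    hw_cb = float(cb["ci_hi"] - cb["effect"]) if np.isfinite(cb["ci_hi"]) else 0.0

    label = "complex"
    single_sig = int(s_uv) + int(s_dr)
    if single_sig == 1 and not s_cb:
        label = "uv_effect_lost" if s_uv else "drought_effect_lost"
    elif s_cb and single_sig == 0:
        label = "combined_only_dose_dependent"
    elif single_sig == 2 and np.sign(e_uv) != np.sign(e_dr) and not s_cb:
        label = "additive_opposite_xor"
    elif (
        single_sig == 2
        and np.sign(e_uv) == np.sign(e_dr)
        and s_cb
        and abs(e_cb - (e_uv + e_dr)) <= hw_cb + _ATOL
    ):
        label = "additive_or"
    elif single_sig == 1 and s_cb and abs(e_cb) > abs(e_uv + e_dr) + hw_cb + _ATOL:
        label = "synergistic"
    elif single_sig == 1 and s_cb:
        e_single = e_uv if s_uv else e_dr
        if np.sign(e_cb) == np.sign(e_single) and abs(e_cb - e_single) <= hw_cb + _ATOL:
            label = "independent_consistent"
    return GatePatternCall(locus=locus, observed_label=label, evidence=effects)


def expected_pattern(gate: str, effect_uv: float = 1.0, effect_drought: float = 0.0) -> str:
    """Pattern label the gate theory predicts for a generating mechanism.

    For the independent gate the prediction depends on how many stress
    inputs the locus has: a single input predicts a consistent effect in
    that stress and the combined treatment; two inputs are observationally
    additive (the OR prediction).
    """
    if gate not in GATES:
        raise InvalidArgumentError(f"unknown gate {gate!r}; expected one of {GATES}")
    if gate == "AND_gate":
        return "combined_only_dose_dependent"
    if gate == "XOR":
        return "additive_opposite_xor"
    if gate == "attenuator_UV":
        return "uv_effect_lost"
    if gate == "attenuator_drought":
        return "drought_effect_lost"
    # independent / OR_gate
    both = effect_uv != 0 and effect_drought != 0
    if gate == "OR_gate" or (gate == "independent" and both):
        return "additive_or"
    return "independent_consistent"


def classify_scan(
    per_locus_effects: Mapping[str, pd.DataFrame],
    truth: Optional[TrueArchitecture] = None,
) -> list[GatePatternCall]:
    """Classify many loci; attaches theory-expected labels when truth is known."""
    expected = {}
    if truth is not None:
        expected = {
            q.marker: expected_pattern(q.gate, q.effect_uv, q.effect_drought) for q in truth.qtl
        }
    calls = []
    for locus, eff in per_locus_effects.items():
        call = classify_locus(eff, locus=locus)
        if locus in expected:
            call = GatePatternCall(
                locus=call.locus,
                observed_label=call.observed_label,
                evidence=call.evidence,
                expected_label=expected[locus],
            )
        calls.append(call)
    return calls


def architecture_fit_report(
    calls: Sequence[GatePatternCall],
    truth: Optional[TrueArchitecture] = None,
) -> dict:
    """Tabulate observed pattern labels, and a confusion matrix versus the
    theory-expected labels when the generating architecture is known.

    Returns ``{"counts": Series, "confusion": DataFrame | None,
    "recovery": Series | None}``; recovery is the per-expected-label
    fraction of matching observed labels.
    """
    if len(calls) == 0:
        raise InvalidArgumentError("need at least one locus call")
    counts = pd.Series([c.observed_label for c in calls]).value_counts()
    confusion = None
    recovery = None
    labelled = [c for c in calls if c.expected_label is not None]
    if truth is not None and labelled:
        df = pd.DataFrame(
            {
                "expected": [c.expected_label for c in labelled],
                "observed": [c.observed_label for c in labelled],
            }
        )
        confusion = pd.crosstab(df["expected"], df["observed"])
        recovery = (
            df.assign(hit=df["expected"] == df["observed"]).groupby("expected")["hit"].mean()
        )
    return {"counts": counts, "confusion": confusion, "recovery": recovery}
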