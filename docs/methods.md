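# Methods

`stressgate` studies how two abiotic stresses — drought and ultraviolet (UV)
radiation — combine to produce growth phenotypes in maize mapping
populations, by simulation and by re-analysis machinery: a genotype /
phenotype simulator whose QTL act through explicit signal-combination
gates, a single-marker genotype × environment scan, a P-value smoothing and
FDR stage, a joint stepwise selection procedure for multiparent designs
with a simulation-based calibration of its entry threshold, a
cross-environment pattern classifier, and an interval-overlap permutation
test.

## The gate model

Each simulated QTL is a biallelic locus (allele `A` from the common/reference
parent, `B` from the alternate parent) whose *half-difference* effect
`a` — the deviation of the allele-A class mean from the population mean, so
the A-vs-B class difference is `2a` — depends on the treatment environment
(`control`, `drought`, `UV`, `combined`) through one of six gates:

| gate                 | control | drought | UV   | combined      |
|----------------------|---------|---------|------|---------------|
| `independent`        | 0       | a_d     | a_u  | a_u + a_d     |
| `OR_gate`            | 0       | a_d     | a_u  | a_u + a_d     |
| `AND_gate`           | 0       | 0       | 0    | a_c           |
| `XOR`                | 0       | −a_u    | a_u  | 0             |
| `attenuator_UV`      | 0       | 0       | a_u  | 0             |
| `attenuator_drought` | 0       | a_d     | 0    | 0             |

`independent` and `OR_gate` share the additive rule; they differ in which
inputs are nonzero (a separate-pathway locus typically has a single stress
input, an integrator responds to both) and therefore in the detection
pattern theory predicts.  The attenuator gates encode a constitutive sensor
for one stress that represses the other pathway's signal, so a single-stress
allelic difference becomes invisible under combined stress — the "UV effect
lost" / "drought effect lost" signature.  All gates are silent in the
control environment; constitutive growth loci are outside the gate model
and are excluded from classification.

The half-difference convention matters: other tools report the full
allele-class difference, a factor of 2 larger.

## Synthetic populations

Meiosis uses the Haldane map function (recombination fraction
`r = (1 − exp(−2d/100))/2` over `d` cM, no crossover interference);
chromosomes assort independently.  Line construction is explicit: F1
hybrids, an optional number of random intermating generations (immortalised
intermated populations in the style of the maize IBM panel; default 4 for
the `ibm` design), then five generations of single-seed-descent selfing,
with residual heterozygosity resolved by transmitting one final gamete (a
linkage-respecting fair coin at each remaining heterozygous locus).  For a
non-intermated selfed RIL the recombinant line fraction between two markers
converges to the fixation limit `2r/(1+2r)`; the simulator matches this to
within ±0.001 at 20,000 lines, and intermating strictly increases the
recombinant fraction at fixed map distance.

The NAM-like design simulates several independent biparental RIL families
(default 5 × 50 lines, the subset size used in the motivating experiment)
sharing allele `A` as the common parent.  Phenotypes follow

    value = trait_mean + block(block, environment)
            + Σ_q s(line, q) · e(q, environment) + ε,

with `s = ±1` for alleles A/B, `e` the gate rule above, block effects drawn
once per (block, environment) cell from N(0, block_sd²) — replicate blocks
are month-replicates crossed with treatments, so each treatment × block
bench gets its own level — and ε ~ N(0, residual_sd²).  Defaults:
trait_mean 10, block_sd 0.5, residual_sd 1 (trait units); 92 lines × 4
blocks for the biparental design and 5 × 50 lines × 2 blocks for the
NAM-like design, mirroring the replication of the motivating greenhouse
experiments.  Missing genotypes are generated only when configured (default
none) and propagate to missing phenotypes rather than being imputed.

Effect sizes are set from variance-explained targets.  Two conventions are
supported because stated per-QTL effect sizes often sum past 100%: `joint`
(`a_i²/(Σa_j² + σ²) = t_i`, requires Σt < 1) and `marginal`
(`a_i²/(a_i² + σ²) = t_i`, each QTL against the residual alone).  The
calibration study uses marginal targets, the only feasible reading of five
QTL spanning 50% down to 8%.

What the generator does **not** emulate: segregation distortion, genotyping
error, non-normal or heteroscedastic residuals, epistasis between QTL
(gates combine *stresses within* a locus, not loci), allelic series in the
NAM families (each family gets the same ±a contrast), and
genotype-dependent missingness.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to these features of real data.

## Genome scan

For each marker the fixed-effects model

    value ~ block + block:environment + environment + allele + allele:environment

is fitted by least squares with sum-to-zero contrasts and the type-III
F-test P for `allele:environment` recorded (a marker main-effect P is kept
alongside, to separate stress-specific loci from constitutive ones).
Blocks are coded within environment because the generator (and the
greenhouse design it emulates) gives each treatment × block cell its own
level; an additive-only block term would leave that fixed pattern in the
error and make the interaction test conservative.  Block × marker terms are
pooled into error.  Markers whose minor allele class has fewer than two
lines are flagged and reported with missing P values.  Rows with missing
genotype or phenotype are dropped listwise per marker.

Per-environment allele effects are least-squares means expressed as
deviations from the environment mean, estimated by an environment-specific
regression `value ~ block + allele(±1)` — for balanced data the coefficient
equals half the class difference — with classical SEs and t-based 95% CIs.
"Significant" throughout means the 95% CI excludes zero.  On a perfect fit
(zero residual, e.g. noiseless simulations) the CI has zero width and
effects smaller than 1e-9 are treated as exact zeros.

An interaction variance component (the allele × environment slope treated
as random) is available as a diagnostic, estimated by moments from the four
per-environment effects; with only four environments it is a coarse
summary and the F-test is the primary statistic.

Artificial coinheritance is screened by flagging pairs of significant
markers on different chromosomes with genotype |r| above a threshold
(default 0.5).

## Smoothing, FDR and interval calling

Each marker's P value is combined with its within-chromosome neighbours in
a sliding window (default width 3; windows shrink symmetrically at
chromosome ends and never cross chromosome boundaries) using either Simes
(`min_k w·p_(k)/k`, capped at 1; default) or Fisher (`P(χ²_{2w} ≥ −2Σln p)`).
Benjamini–Hochberg q-values are computed on the smoothed values and maximal
runs of markers with `q < α` merged into QTL intervals, peak = minimum-q
marker.  Widening the window raises power at QTL flanked by correlated
markers at the cost of broader intervals; both are tested.

A fractional-rank pre-transform (`rank/(n+1)`, average ranks for ties) is
implemented and exposed (`rank_transform=True`) but **off by default**: the
smallest achievable rank is `1/(n+1)`, so a rank-transformed and
Simes-combined value is at least `≈ w/(n+1)` and BH correction then returns
q ≈ 1 for every marker no matter how strong the signal.  The transform is a
robustness device for *ordering* markers when raw P values are miscalibrated;
calibrated significance requires smoothing the raw P values, which is what
the default pipeline does.

Correlated adjacent markers can optionally be clustered (greedy merge at
genotype r² above a threshold, most-complete member as representative)
before scanning, mirroring the practice of analysing a unified
representation of coinherited marker groups.

## Joint stepwise selection and its calibration

For multiparent data the model is fitted jointly across families: the base
model has family, environment, block and block-within-environment fixed
effects; a candidate term for marker m adds family-nested allele columns
`s_m·1[family=f]` plus their environment interactions (family-specific
allele effects; no allelic-series constraint).  Forward selection enters,
at each step, the candidate with the smallest joint F-test P value
(conditional on the current model) if it beats the entry threshold SLE, and
stops otherwise or at `max_terms`.  Selection at a stricter threshold is a
prefix of the same greedy path, which the implementation exploits to
evaluate a whole SLE grid from one run per simulation.  Candidate screening
is vectorised across markers with rank-aware generalised inverses, so
monomorphic-within-family markers simply contribute fewer degrees of
freedom.  Missing genotype signs are imputed to 0 (the allele mean) so all
candidates share one observation basis.

The calibration study re-creates the published simulation experiment: five
QTL with marginal variance targets linearly spaced 50% → 8% are placed at
random markers of a fixed panel (default 500 markers on 10 × 150 cM
chromosomes — the real marker count is not public, so density is a
documented package default), phenotypes simulated under the NAM design, and
selection run at each SLE on the grid.  One genotype panel is simulated per
calibration and reused across simulations, matching a fixed experimental
population; each simulation draws fresh QTL positions and phenotypes.  A
selected marker within `tp_window` cM (default 10) of a still-unclaimed
true QTL on the same chromosome is a true positive (entry order, each QTL
credited once); other selections are false positives; unclaimed QTL are
false negatives.  Counts aggregate over simulations into PPV = TP/(TP+FP),
sensitivity = TP/(TP+FN) and FDR = 1 − PPV.  `best_sle` maximises
sensitivity subject to FDR ≤ 0.10, ties to the stricter threshold; under
these defaults sensitivity saturates at 1 for every grid point at or below
0.01, so the constraint binds through FDR and the strictest threshold wins
ties.

## Pattern classification

A detected locus is labelled from its per-environment (effect, significance)
evidence by ordered rules: (1) significant in exactly one single stress and
not in combined → `uv_effect_lost` / `drought_effect_lost`; (2) combined
only → `combined_only_dose_dependent`; (3) both single stresses with
opposite signs, combined not significant → `additive_opposite_xor`;
(4) both single stresses, same sign, combined significant and within the
combined CI of the single-effect sum → `additive_or`; (5) one single stress
plus combined exceeding the summed singles beyond the combined CI →
`synergistic`; (6) one single stress plus combined of consistent sign and
magnitude within the combined CI of that single effect →
`independent_consistent`; (7) otherwise `complex`.  The synergy rule
(CI-based super-additivity) is this package's operationalisation — the
motivating analyses label synergy without stating a criterion.  Independent
and OR generating mechanisms are distinguishable only through how many
single-stress inputs show effects; with both inputs active an independent
locus is observationally additive and theory predicts the OR label.

Loci with a significant control-environment effect are refused by the
classifier (constitutive, not stress-specific); the pipeline drops them
before classification.

## Interval-overlap permutation test

The chance that `k` of the intervals in set A overlap set B is assessed by
re-placing A's intervals (lengths preserved) uniformly on the genetic map —
chromosome drawn proportional to length among chromosomes that can hold the
interval, start uniform over the valid range, closed intervals — and
reporting `p = (1 + #{perms ≥ observed})/(n_perm + 1)`.  The estimator is
validated against closed-form placement probabilities on single-chromosome
maps.

## Variance components

Per trait and environment, `value_ij = μ + line_i + ε_ij` is fitted by REML
(statsmodels MixedLM; components truncated at zero, with an
expected-mean-squares fallback using the unbalanced-design coefficient
`n0 = (N − Σn_i²/N)/(k−1)`).  The line percentage
`100·v_line/(v_line+v_error)` is reported to one decimal and left blank
when `v_line = 0` — a zero genetic component makes the share uninformative
rather than 0.  Line components below a relative 1e-7 of the total are
treated as boundary zeros.

## Numerical choices and problem sizes

Sum-to-zero contrasts throughout; perfect fits detected at relative SSE
1e-10 (interaction P set to 0 when the dropped term carries signal, missing
when not); eigenvalue cutoff for candidate-term rank `K·1e-9·λ_max`; effect
atol 1e-9.  All randomness derives from a single root seed through
`numpy.random.SeedSequence` spawning, making every stage bit-reproducible.

Simulation-based tests use deliberately modest sizes chosen to give the
tested contrasts clear margins at desk scale: 2000 lines for recombination
fractions, 500 null simulations for the interaction test's type-I error,
400 simulations for CI coverage, 200 simulations for the headline SLE
calibration (with a 30-simulation grid for the monotonicity property), and
a 6-gate noiseless run for exact end-to-end recovery.

## Known limitations

- The biparental scan is single-marker; no composite-interval or multi-QTL
  models, so closely linked QTL produce merged or shadowed intervals.
- BH is applied to window-smoothed, hence locally correlated, values;
  calls at a nominal FDR are somewhat anticonservative under strong local
  correlation, and occasional shadow intervals appear on chromosomes
  carrying a strong QTL.
- With four environments the random-slope interaction variance is a rough
  diagnostic only.
- Gate classification is a per-locus decision rule on point estimates and
  CIs; it does not propagate uncertainty into the label (a borderline
  `additive_or` vs `synergistic` call can flip with the draw).
- The overlap test's null ignores linkage structure within interval sets
  (uniform placement, independent intervals).
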