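# Methods

## Data model

One agar plate per row: a harvested developmental spot (pair or pure
culture, nutrient history of each partner, replicate) plus the selection
agent, the dilution (as a fraction), plated and harvest volumes, and the
colony count. The plated fraction — the share of the harvested sample
represented on the plate — is always computed as
`dilution × volume / harvest volume`, never supplied directly, which makes
it invariant to how volumes are bookkept. The harvest volume is a required
column: assays differ in the volume spots are collected into, and guessing
it silently rescales every spore total. Uncountable lawns are recorded with
`countable = false` and excluded from pooling rather than truncated or
guessed.

## Spore estimation

Plates of one sample and selection are pooled with the Poisson maximum
likelihood estimator `N̂ = Σ colonies / Σ plated_fraction`: each plate's
count is Poisson with mean `N·f`, so the summed count is sufficient for `N`.
The estimator reduces to the single-plate rule `c/f` and is exactly unbiased.
Pooling across dilutions is a deliberate choice — using only one "best"
dilution discards information and an ad-hoc average of per-plate estimates
over-weights dilute plates.

**Detection limit.** A sample whose countable plates all show zero colonies
is assigned 0.9 spores, applied once at the pooled-sample level. This keeps
every efficiency positive and every log-ratio finite while marking the value
(`lod_imputed`) so downstream statistics can be read with appropriate
caution; censoring such samples instead would systematically discard exactly
the strongest suppression outcomes. The same 0.9 floor clamps a
by-subtraction estimate when marker counts exceed the non-selective total
(`subtraction_clamped`); the alternative — propagating a negative spore
count — is meaningless.

**Deconvolution.** Directly marked strains take their selective-plate
estimate; at most one strain per pair is obtained as
`total − Σ marked`. Antibiotic selection is assumed not to alter colony
recovery, so no correction factor is applied. Conservation (per-strain
estimates summing to the non-selective total) holds whenever no clamp fires.

**Initial cells.** Spot volume × resuspension density (defaults 0.1 ml ×
5×10⁹ cells/ml = 5×10⁸ cells per spot), split by the mixing ratio for
chimeric spots (2.5×10⁸ each at 1:1; 5×10⁷ / 4.5×10⁸ at 1:9).

## Fitness statistics

`W_ij = log10(spores_i/init_i) − log10(spores_j/init_j)` within one spot;
the two ordered records of a spot are exact negations.
`C_i(j) = log(D_i(j)) − log(D_i)` compares a strain's efficiency in the mix
to its pure culture grown under the same nutrient history. The logarithm
base for C is a configuration knob defaulting to 10, matching W; every
sign-based conclusion is base-invariant. The pure-culture reference is taken
from the same replicate when available (replicates are temporally separate
experiments, so they share batch effects); otherwise the geometric mean of
the available pure replicates is used and the record flagged
(`pure_ref_fallback`) — the geometric mean, not the arithmetic one, because
the statistic lives on the log scale.

The fitness table holds one row per ordered focal strain per mixed spot, so
both partners' mixing effects are first-class rather than derived.

## Inference

Responses are log-scale continuous statistics, so "generalised linear
model" here means a Gaussian identity-link linear model; its F-table is the
classical factorial ANOVA. Defector pairs are analysed jointly on the
defector's W with genotype × focal history × partner history (all 1-df terms
with two genotypes and two history levels); isolate pairs per focal strain
on C with history × history. Empty design cells make the full-factorial
model unidentifiable, so the fit is refused with the cells named. Type III
sums of squares, when requested, use sum-to-zero contrasts; on balanced
designs all three types coincide.

Per family (pair × focal strain × statistic), the four history cells are
tested against zero with two-sided one-sample t-tests, Holm-corrected within
the family (α = 0.05, configurable; a `global` family policy pools all
cells of the experiment instead, and the chosen policy is recorded in the
output). History effects are tested with Tukey HSD over all cell pairs or
Dunnett contrasts against the H/H reference; both assume equal cell
variances, as their standard constructions do.

**Degenerate cells.** When every replicate of a cell is identical (the
generator's expectation mode), the t statistic is undefined; the result is
reported degenerate with no p-value, and significance is decided by the
exact sign of the constant value. A constant zero is never significant. In
noisy data this path can only trigger when all four replicates hit the same
detection floor — such calls carry the LOD flag and should be read as
"qualitatively at the floor", not as precise effects.

**Verdicts.** `+` requires a significantly positive mean; `antagonized` a
significantly negative one; otherwise `-`. A `+` cell whose Dunnett contrast
against H/H shows a significant decrease is `reduced-but-present`.
Classification is a pure function of the test results.

## Synthetic experiments

The generator emulates the assay structure — pure cultures of every strain
under both histories plus every pair × history cell, four replicates,
selective and non-selective dilution plating — on a minimal latent model:

    log10 D(strain, spot) = base(strain, history)
                            + interaction delta (mixes only)
                            + Normal(0, sigma_rep)
    plate counts ~ Poisson(spores × plated fraction)

Interaction deltas act additively on the focal strain's log10 efficiency, so
true values are closed-form: W is the difference of the two mix latents and
C_i(j) is exactly strain i's delta. `expectation` mode disables both noise
sources and emits exact real-valued expected counts, giving 1e-9-level
end-to-end oracles; `full` mode is the stochastic study condition. There is
no overdispersion term beyond the replicate effect, and no mechanistic model
of development (signalling, lysis, timing) — the generator reproduces the
statistical structure of the data, not its biology. Consequences: passing
tests certify the pipeline's arithmetic and calibration under
log-normal-plus-Poisson noise, not the adequacy of that noise model for any
particular wet dataset.

Defaults, chosen once as realistic study conditions: four replicates;
`sigma_rep = 0.2` log10 units (a plausible between-replicate spread for
temporally separate developmental assays; the value is a modelling choice,
not an empirical claim); plating as a half-log dilution series 10⁻²…10⁻⁶ in
duplicate (0.1 ml plated of a 1 ml harvest, countability cap 400 colonies) —
standard practice when counting precision matters, leaving four to six
countable plates per sample and a detection floor of 1000 spores.

**Presets.** `cheater_pairs` encodes two defectors (pure-culture efficiency
10⁻⁶, a few hundred spores per spot, straddling the detection floor) against
a cooperator at 10⁻², mixed 1:9: Ch1 cheats only when the cooperator grew at
high nutrients (W = +1.1 in H/H and L/H, −1.2 otherwise), Ch2 fails to cheat
only in L/L (+1.1/+1.05/+1.0/−1.2). Effect sizes keep mix efficiencies below
1 and the cooperator a substantial share of total spores — as in real assays
with W of order 1 — which keeps its by-subtraction estimate well
conditioned; the intended grid is then recoverable from noisy runs with the
stated σ and n. `natural_isolates` encodes three proficient strains at 1:1
with a dominance hierarchy: strain G suppressed ~4.5 log10 units in every
mix (< 0.01% of total spores, typically at the detection floor, so its
measured C is an LOD-flagged lower bound), D exploiting G only under H/H,
and I exploiting G in three of four cells.

The recovery report re-simulates a configuration many times, runs the full
pipeline, and summarises bias and RMSE of the cell-mean W/C plus empirical
`+`-call rates — power under true effects, type-I error under nulls.

## Problem sizes

Validation uses the sizes the pipeline is built for: single experiments of
~1600–2500 plates analyse in well under a second; calibration checks use 500
simulated null experiments (type-I error of `+` calls ≤ α plus Monte-Carlo
slack) and 120 full-noise preset runs (qualitative grid recovery ≥ 90%).

## Known limitations

- No most-probable-number or truncated-count corrections for crowded plates;
  lawns are simply excluded.
- The 0.9-spore substitute is a point imputation; no censored-likelihood
  treatment of detection-limited samples.
- Tukey/Dunnett rely on equal-variance assumptions; heavy LOD involvement
  violates them, and such cells are flagged rather than re-modelled.
- Subtraction-based estimates degrade when the marked strain dominates the
  total; the clamp guarantees positivity, not accuracy, in that regime.
- Single developmental episode only: no population dynamics across cycles.
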