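# Methods

## Dose-response model and estimator

Every endpoint series is reduced to the power model FE = (Dose + 1)^β,
where FE is the fold-effect over the within-experiment control mean and β
is dimensionless. Taking logs gives log FE = β·log(Dose + 1) with no
intercept — at dose 0 the model passes through FE = 1 by construction — so
the default estimator is the closed-form slope

    β̂ = Σ log(FE)·log(Dose+1) / Σ log(Dose+1)²

over all replicate points pooled (replicates enter individually rather than
as per-dose means, preserving replicate weighting). This is the exact
least-squares and maximum-likelihood solution under multiplicative
lognormal noise, is reproducible without an iterative solver, and makes
dose-0 points carry zero leverage, so whether they are included is
immaterial. A bounded scalar minimization of the raw-scale residual sum
Σ(FE − (Dose+1)^β)² is provided as `nonlinear_ls`; the two agree to < 1e-8
on noise-free power-law data and the suite verifies the closed form against
a 1e-5-step grid search of the log-scale RSS.

The standard error uses the log-scale residual variance with n − 1 degrees
of freedom (one fitted parameter, no intercept). Non-positive fold-effects
(possible in background-subtracted assay data) are floored at 1e-12 before
logging, with a logged warning. A series needs at least two distinct
nonzero doses with usable FE; anything less is reported as an explicit
`insufficient_data` outcome, never as β = 0.

## Fold-effect normalization

FE = value / grand mean of all dose-0 values in the same experiment, same
endpoint, same unit. Controls are pooled across particles within an
experiment by default (plates share their dose-0 wells); a `per_particle`
policy exists for designs with particle-specific vehicle controls. Missing
values are excluded from control means and propagate as missing FE; a group
whose controls are all missing gets missing FE throughout (with a warning)
so the downstream fit reports `insufficient_data` instead of the series
silently vanishing. Normalizing to the control *arithmetic* mean of
lognormal replicates introduces a small negative bias in β̂ of order
σ²/2 · Σx/Σx² (x = log(dose+1)); at σ = 0.2 with the default design this is
≈ −0.003, measured below, and is a property of the grand-mean normalization
itself rather than of the estimator.

## Index hierarchy

All combined indices are arithmetic means of their declared inputs; missing
inputs shrink the denominator (never zero-filled) and input counts are
reported. Per cell line: β_V (mean over LDH, resazurin, ATP, BrdU slopes),
β_R (mean of their absolute values), β_I−V HI/LO (signed mean of
viability-adjusted cytokine slopes, denominator = number of non-missing
cytokines, identical in both scenarios — hence HI − LO = 2·β_IL6/n
exactly). Across cell lines: β_V CELLS and β_I−V HI/LO average the units;
β_R CELLS additionally includes the AhR reporter slope divided by 20. The
AhR term is configurable in two respects the source procedure leaves open:
whether it enters β_R CELLS at all (`include_ahr_in_reactivity`, default
true, matching the definition used for the combined reactivity estimate)
and whether it enters signed or absolute (`ahr_abs_in_reactivity`, default
absolute, consistent with reactivity counting any deviation from baseline).
The /20 factor relates reporter luminescence magnitudes to the other
endpoints and is exposed as `ahr_factor`.

In vivo, β_T is the sign-weighted mean over BAL protein, LDH,
8-isoprostane, neutrophils, macrophages, band cells and lymphocytes.
Macrophages carry sign −1 (loss of resident alveolar macrophages marks
potency); lymphocytes and band cells, which increase on exposure, carry +1
— the source material does not enumerate these signs, so the map is
explicit configuration and the suite demonstrates that flipping a sign
changes the index. β_I applies the HI/LO scheme to raw in vivo cytokine
slopes (no viability adjustment exists in vivo), and Iβ = mean(β_T, β_I).

Ranking assigns rank 1 to the largest index value (most potent); ties take
midranks.

## Correlation and p-values

Pearson is the product-moment coefficient; Spearman is Pearson on midranks,
identical to 1 − 6Σd²/(n(n²−1)) for untied ranks (the suite checks the two
routes agree to 1e-12 and cross-checks against `scipy.stats.spearmanr`).
p-values default to the t transform t = r√((n−2)/(1−r²)) on n − 2 degrees
of freedom, halved for a one-tailed test in the positive direction — this
is the convention under which the shipped five-particle rank analysis
yields p = 0.052 at ρ = 0.8, n = 5 and p = 0.100 at ρ = 0.8, n = 4. An
exact permutation p (proportion of all n! rank permutations at least as
concordant) is available for n ≤ 8 and gives 0.0667 at ρ = 0.8, n = 5; it
is the better-calibrated choice at these sample sizes but is offered as the
alternative, not the default, to match the published convention. At
|r| = 1 the t statistic diverges and p is reported as 0.

One discrepancy is documented rather than matched: the originally printed
all-particle toxicity coefficient (0.667) is not what the printed rank
vectors (5,4,2,1,3) vs (3,5,2,1,4) give — both the Σd² formula and
Pearson-on-ranks yield 0.700. The printed value is consistent with a tie
between two particles in the underlying in vivo values (midranks 4.5/4.5
give 0.667); since only the integer ranks are available as inputs, the
package reports 0.700.

## Synthetic-data generator

The generator emulates the screening study design the analysis assumes:

- in vitro doses {0, 10, 20, 40, 80, 160} µg/well, 3 independent
  experiments × 3 replicate wells (configurable), two cell lines with four
  viability assays and their cytokine panels (A549: GM-CSF, IL-1β, IL-6,
  IL-8, IL-10, MCP-1, MIP-1β, TNF-α; J774A.1: GM-CSF, IL-1α, IL-1β, IL-6,
  IL-10, RANTES, TNF-α), plus an AhR reporter line;
- in vivo doses {0, 50, 100, 250} µg with 5 animals per dose and BAL
  toxicity markers plus cytokines.

Values are baseline × (dose+1)^β_true × exp(ε) with ε ~ N(0, σ²);
σ defaults to 0.2 on the log scale. Replicate-level variance is not
reported for most real endpoints, so this default is a plausible mid-range
choice, not a claim about any particular assay. Cytokine baselines are
typical control-supernatant levels; baselines cancel in fold-effect, so
they only set display scale (verified by a scaling-invariance test).
Dose-0 wells are simulated once per experiment and shared across particles,
matching the pooled-control normalization. Urban particles draw endotoxin
within 3–127 EU/µg with one pinned low-endotoxin (3.0 EU/µg) sample;
minerals carry none. True slopes are drawn uniformly from per-role ranges
(viability −0.25..0, pro-inflammatory 0..0.35, anti-inflammatory
−0.15..0.10, dual −0.10..0.35, AhR −0.5..2.0, in vivo markers 0..0.30,
macrophages −0.30..0), overridable per endpoint.

What the generator does **not** emulate: plate-position effects, particle
settling or optical interference with readouts, inter-assay calibration
drift, correlated noise across endpoints, and real particles' composition-
driven effect structure. Passing tests therefore demonstrate that the
computational chain recovers known truths under its own statistical
assumptions — not that those assumptions hold for any particular assay.

## Calibration results and problem sizes

With σ = 0.2, the default dose grid, 3 experiments × 3 replicates (200
simulations, 1200 fits): mean bias of β̂ ≈ −0.003 (the grand-mean
normalization term above) and RMSE ≈ 0.019, falling to ≈ 0.014 and ≈ 0.010
at 6 and 12 replicates. A 5-experiment design at β_true = 0.05 puts 95 % of
fits within ±0.026 of the truth; the suite asserts coverage at ±0.03.
Calibration studies in the tests and acceptance script use a compact
one-unit, three-endpoint, two-particle design — estimator precision is set
by the replicate structure, not panel width — keeping the 200-repetition
studies in seconds. The zero-noise end-to-end study uses five particles
whose in vitro slopes are proportional to a scalar potency score and whose
in vivo slopes use the monotone transform s^1.5 of the same scores; every
integrated index is then a positive multiple of the score, so perfect rank
concordance (Spearman = 1 on every pair) is the known correct answer.

## Numerical and interface choices

- Tables are written as TSV (CSV selectable) with `#`-prefixed header lines
  carrying the seed and package version; floats at full precision (%.12g) —
  a single authoritative representation rather than a rounded display
  column plus a full-precision duplicate.
- Spearman coefficients within 1e-12 of ±1 are snapped to ±1 (attainable
  rank correlations at small n are widely separated, so this only removes
  float noise from perfectly concordant ranks).
- Determinism: identical (design, panel, seed) triples produce
  byte-identical output tables; the in vivo simulation uses seed + 1 to
  decouple its noise stream from the in vitro one.
- The CLI (`pmpotency simulate|foldeffect|fit|integrate|correlate|run-all`)
  is a thin layer over the library; exit codes are 0 (success),
  2 (validation/configuration), 3 (computation).

## Known limitations

- The power model is a one-parameter summary: it cannot represent
  non-monotone dose-response (e.g. low-dose stimulation with high-dose
  toxicity) except as an averaged slope.
- The t-approximation p is anti-conservative at n = 4–5 relative to the
  exact permutation test; it is retained as the default for comparability,
  with the exact test one keyword away.
- Equal-weight averaging is the only aggregation scheme; endpoints with
  very different signal-to-noise contribute equally.
- MIP-1α in the macrophage cytokine panel is excluded (above assay limit in
  the reference design); benchmark-dose or EC50 estimation and ANOVA-based
  dose-sensitivity screening are out of scope.
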