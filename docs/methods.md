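# Methods

`mr2s` implements summary-level two-sample Mendelian randomization (MR):
causal-effect estimation for an exposure→outcome pair from two
independent GWAS, using genetic variants as instrumental variables. This
note records the statistical model, the conventions and defaults chosen
where the literature leaves them open, what the synthetic-data generator
does and does not emulate, and known limitations.

## Data model

For each SNP *j* the inputs are the exposure association
(β̂ˣⱼ, σˣⱼ) and the harmonized outcome association (β̂ʸⱼ, σʸⱼ), both
per-allele additive effects of the same effect allele. The working model
is

  β̂ˣⱼ = γⱼ + uⱼ,  uⱼ ~ N(0, σˣⱼ²)
  β̂ʸⱼ = θ γⱼ + αⱼ + vⱼ,  vⱼ ~ N(0, σʸⱼ²)

with θ the causal effect (log odds per unit of exposure), γⱼ the true
instrument effect and αⱼ a horizontal-pleiotropy (direct) effect, zero
for a valid instrument. The three IV assumptions are: relevance
(γⱼ ≠ 0, enforced by significance selection and the F screen),
independence from confounders, and exclusion restriction (αⱼ = 0);
only the first is testable here, and the diagnostics battery probes
departures from the third.

## Instrument selection

Instruments are exposure SNPs with p < 5×10⁻⁸, pruned by greedy LD
clumping: repeatedly take the smallest-p remaining SNP as an index and
remove same-chromosome SNPs within the window (default 10,000 kb,
half-open |Δpos| < window) whose r² with the index exceeds the threshold
(default 0.001). Ties on p are broken by (chrom, pos), so the result is
independent of input order. The package consumes a precomputed pairwise
r² table; pairs absent from the table are treated as unlinked (r² = 0)
and counted. Without a table, pruning is by distance alone, with a
prominent warning — this is deliberately aggressive (it keeps one SNP
per window) because keeping correlated instruments silently would be
worse than keeping too few.

Instrument strength is F = R²(n−2)/(1−R²). The per-SNP R² convention
defaults to `z_based`, R² = z²/(n−2+z²) with z = β̂/σ̂, under which F is
exactly z²; this needs no assumption about the exposure's measurement
scale. The alternative `variance_explained` convention,
R² = 2p(1−p)β̂², is exact only for a trait standardized to unit
variance. On published per-SNP tables the two conventions bracket the
printed F values to within a few percent but neither reproduces them
exactly (per-locus sample sizes likely differ), so F values are reported
rather than asserted. F < 10 flags (not drops, unless strict mode) a
weak instrument; the reported mean F is the unweighted arithmetic mean.

## Harmonization

SNPs are matched across the two GWAS by rsID only. Four allele
configurations are reconciled: identical; swapped (outcome β sign and
eaf flipped); strand complement; strand complement plus swap.
Palindromic SNPs (A/T, C/G) cannot be strand-resolved from labels, so
allele frequency is used: the outcome eaf is first expressed on the
exposure's effect allele (flipping when labels are swapped), and the SNP
is kept only when both frequencies lie on the same side of 0.5 and
outside the ambiguity zone (limit, 1−limit), default limit 0.42 (i.e.
within 0.08 of 0.5 is ambiguous). Frequencies on opposite sides of 0.5
suggest a strand flip or population mismatch and the SNP is dropped
rather than "corrected" — a conservative choice, since a wrong strand
call silently flips the effect sign. Dropped rows stay in the harmonized
table with a labelled `dropped_*` action for audit and never enter
estimation.

The per-SNP Wald ratio is β̂ʸ/β̂ˣ with first-order SE σʸ/|β̂ˣ|. The
delta-method SE ignores exposure-side error; it is within ~10% of a
parametric-bootstrap SE whenever |β̂ˣ|/σˣ > 10, which the F screen
guarantees.

## Estimators

* **IVW** — weighted regression of β̂ʸ on β̂ˣ through the origin,
  weights 1/σʸ²; equivalently the inverse-variance-weighted mean of Wald
  ratios. Fixed-effect SE = (Σ β̂ˣ²/σʸ²)^(−1/2); the
  multiplicative-random-effects variant multiplies it by
  √max(1, Q/(J−1)) and is the usual primary analysis. The clamp at 1
  means the random-effects SE never undercuts the fixed one; it makes
  the test mildly conservative under the null (rejection ≈ 0.04 at
  α = 0.05), which we accept.
* **Weighted median** — order Wald ratios, standardize the cumulative
  weights sⱼ = (Σₖ≤ⱼ w₍ₖ₎ − w₍ⱼ₎/2)/Σw, linearly interpolate the ratio
  at s = 0.5. Consistent while valid instruments carry > 50% of total
  weight. SE by seeded parametric bootstrap (default 1000 draws
  perturbing both β̂ˣ and β̂ʸ by their SEs).
* **MR-Egger** — weighted regression with a free intercept after
  orienting every instrument to β̂ˣ ≥ 0. The intercept estimates average
  directional pleiotropy; the slope is consistent under InSIDE
  (instrument strength independent of direct effects). Both SEs carry
  the residual scale √max(1, Q′/(J−2)); p-values use t with J−2 df
  (small-J robustness). Orientation happens inside the estimator and
  never mutates the harmonized table.
* **MR-Egger with SIMEX** — corrects Egger's regression dilution when
  exposure effects carry non-negligible error (NOME violation, low
  I²_GX): for each λ in {0, 0.5, 1, 1.5, 2}, add N(0, λσˣ²) noise to
  β̂ˣ over B replicates (default 1000), average the refitted Egger
  estimates per λ, fit a quadratic in λ and extrapolate to λ = −1. The
  SE combines the plain Egger SE with a delete-one-replicate jackknife
  of the extrapolant in quadrature (the jackknife captures only the
  simulation noise). The method reference fixes no settings; grid,
  extrapolant degree and B are declared defaults.

Odds-ratio CIs always use ±1.96·SE on the log scale, independent of the
p-value reference, matching forest-plot convention. All ORs are "per
unit of the deposited exposure beta": summary statistics rarely state
the exposure unit, so the scale is carried as opaque metadata and a
caveat is printed in every report.

## Diagnostics

* Cochran's Q about the IVW slope (χ², J−1 df) and Rücker's Q′ about the
  Egger line (χ², J−2 df); Q′ ≤ Q always since the Egger fit minimises
  the same weighted RSS over a larger model class.
* I²_GX = max(0, (Q_GX − (J−1))/Q_GX)·100, with Q_GX the 1/σˣ²-weighted
  sum of squares of exposure effects about their weighted mean: the
  share of spread in observed exposure effects not due to estimation
  error. Values near 100% mean plain Egger is trustworthy; low values
  motivate SIMEX. This is the I² variant reported in the diagnostics
  table: at typical instrument strength (mean F > 100) a Q-based
  heterogeneity I² would be incompatible with a barely significant
  Cochran test, whereas I²_GX naturally sits in the high 90s.
* MR-PRESSO: observed statistic RSS = Σⱼ wⱼ(β̂ʸⱼ − θ̂₍₋ⱼ₎β̂ˣⱼ)² with
  leave-one-out IVW slopes; its null distribution is built from
  parametric replicates drawing both β̂ˣ* and β̂ʸ* at their SEs. The
  global p is the add-one empirical tail, so p ≥ 1/(n_sim+1). Per-SNP
  outlier p-values are Bonferroni-corrected by J and flagged at 0.05;
  note the corrected empirical p can only reach significance when
  n_sim > J/α. The distortion test compares the slope shift after
  outlier removal against removal of 1000 random same-sized subsets.
  Defaults (n_sim = 1000, α = 0.05, 1000 distortion resamples) are
  declared conventions; the method reference fixes the idea, not
  constants.
* Method selection: heterogeneity (Cochran p < α) selects
  random-effects over fixed-effects IVW; evidence of directional
  pleiotropy (Egger intercept p < α or PRESSO global p < α) promotes
  MR-Egger (plus outlier-corrected IVW when outliers exist) to primary
  with IVW supporting. The verdict is a label; every estimate is always
  reported and no multiplicity correction is applied across estimators.

## Synthetic data generator

`simulate_pair` draws the data model above directly: maf ~
Uniform(0.05, 0.5), γⱼ ~ N(0, γ_sd²), SEs from the standardized-trait
approximation σ ≈ 1/√(2p(1−p)n), independent exposure and outcome
samples (two-sample design, no overlap). Defaults describe the study
conditions the pipeline is meant to emulate: J = 204 instruments,
n_exp = 436,491, n_out = 105,248, θ = 0.12 (OR ≈ 1.13 per exposure
unit), γ_sd = 0.03 — chosen so that E[z²] = 1 + (γ_sd/σˣ)² ≈ 115,
i.e. instrument F statistics averaging near the low hundreds as in
large CRP-scale GWAS panels. With ascertainment on (the default, since
real panels are genome-wide significant) the realized mean F is higher
(~200+) through winner's curse; recovery studies switch ascertainment
off to measure estimator properties without selection bias.

Pleiotropy regimes: `balanced` (zero-mean direct effects), `directional`
(N(α_mean, α_sd²) applied **relative to the exposure-increasing
allele**, i.e. multiplied by sign(γⱼ) — the sign convention under which
the Egger intercept is defined; with allele-symmetric direct effects
"directional" pleiotropy would cancel under orientation), and
`inside_violating` (αⱼ = c·γⱼ + noise, breaking InSIDE). Gross outliers
add a fixed offset (default 0.5) to chosen SNPs. A configurable fraction
of SNPs receives palindromic allele pairs so the harmonization path is
exercised.

What the generator does **not** emulate: LD between instruments (a
block-constant r² table generator exists solely to exercise clumping),
case-control outcome SEs (the standardized-trait SE model is used for
both traits; real binary-trait SEs also depend on case fraction),
population stratification, sample overlap, and per-SNP sample-size
variation. Passing tests therefore demonstrate correctness of the
estimators and their calibration under the stated model, not robustness
to those real-data features.

Two simulation findings worth recording, both intrinsic to the methods
rather than artifacts of this implementation:

* **Orientation pathology.** With *unselected* weak instruments, the
  data-driven β̂ˣ ≥ 0 orientation misorients near-null SNPs; their
  directional direct effects then enter with flipped sign near x = 0,
  biasing the Egger slope upward severely (~3× θ in our checks). An
  ascertained panel (p < 5×10⁻⁸) bounds |β̂ˣ| away from zero and
  removes the pathology; the directional-pleiotropy recovery study
  therefore uses ascertained instruments, as a real analysis would.
* **Weighted-median breakdown.** At 49% invalid weight with a
  *one-sided* large offset the weighted median sits essentially at its
  breakdown point: the estimate is the ≈0.98 weighted quantile of the
  valid-instrument ratio distribution, biased by about two ratio-SDs at
  any noise level. The robustness contract is therefore tested with
  balanced (random-sign) contamination, where the 51% valid weight mass
  keeps the median consistent while per-dataset IVW errors are an order
  of magnitude larger.

## Problem sizes used in the test suite and acceptance script

Calibration uses 2000 null datasets at J = 50 (plus 500 for MR-PRESSO at
300 simulations each); recovery uses 500 replicates at J = 204 and full
GWAS sample sizes; robustness uses 500 contaminated replicates and 200
planted-outlier replicates at 1500–2000 PRESSO simulations. The
acceptance script runs one full GWAS-scale pipeline (J = 204, 1000
PRESSO simulations, 500 SIMEX replicates per λ) plus reduced-size
calibration summaries. These sizes give Monte-Carlo SEs comfortably
below the tolerances being checked while keeping the whole suite under
a minute of compute.

## Numerical choices and degenerate inputs

Egger raises on designs with (numerically) no spread in β̂ˣ, using a
relative tolerance of 1e-12 on the weighted SS. Wald ratios are
undefined at β̂ˣ = 0; such instruments are excluded with a log entry.
SIMEX requires the λ grid to start at 0 and increase strictly; with all
σˣ = 0 it returns the plain Egger fit. Empirical p-values use the
add-one convention throughout. All randomness (median bootstrap, SIMEX,
PRESSO, simulation) flows from explicit seeds and is bit-reproducible.

## Limitations

No LD computation from genotype panels, no proxy-SNP search, no
liftover, no Steiger directionality filtering, no multivariable MR or
mode/contamination-mixture estimators. Matching is by rsID only.
Exposure units are opaque, so ORs are per unit of the deposited beta.
The distortion-test reference distribution and the PRESSO constants are
conventions, not canon; results near the α boundary should be read
accordingly.
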