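# mr2s — two-sample Mendelian randomization from GWAS summary statistics

`mr2s` estimates the causal effect of an exposure on an outcome from two
independent GWAS summary-statistics tables, using genetic variants as
instrumental variables. It was built around the classic epidemiological
question of whether an inflammation marker (such as C-reactive protein)
causally raises the risk of a late-life disease (such as age-related
macular degeneration), but applies to any exposure/outcome pair with
per-SNP association summaries. Its intended users are genetic
epidemiologists and statistical-genetics researchers who want a single
audited pipeline from raw summary files to a forest table — and a
synthetic-data generator that makes every stage testable without
downloading any cohort data.

## What it computes

For harmonized instruments j = 1..J with exposure effects β̂ˣⱼ (SE σˣⱼ)
and outcome effects β̂ʸⱼ (SE σʸⱼ), the per-SNP Wald ratio is
β̂ʸⱼ/β̂ˣⱼ, and the package reports five pooled estimators of the causal
effect θ (log odds of outcome per unit of exposure):

* **IVW** (fixed and multiplicative-random-effects): weighted regression
  of β̂ʸ on β̂ˣ through the origin, weights 1/σʸ²; the random-effects SE
  is inflated by √max(1, Q/(J−1)).
* **Weighted median**: the 50% point of the weight-standardized Wald-ratio
  distribution; robust to <50% invalid weight. Bootstrap SE.
* **MR-Egger**: weighted regression with a free intercept estimating
  average directional pleiotropy; slope consistent under InSIDE.
* **MR-Egger with SIMEX**: simulation-extrapolation correction of Egger's
  regression dilution when exposure effects are measured with error.

Diagnostics: Cochran's Q (IVW heterogeneity), Rücker's Q′ (Egger),
I²_GX (instrument-strength heterogeneity, the NOME gauge), MR-PRESSO
(global pleiotropy test, outlier flagging, distortion test), per-SNP
F statistics with F = R²(n−2)/(1−R²), and a rule-based recommendation
of the primary method. Instrument selection uses the genome-wide
threshold p < 5×10⁻⁸ and greedy LD clumping (r² ≤ 0.001 within
10,000 kb by default) against a precomputed pairwise r² table.

See `docs/methods.md` for every convention and default.

## Worked example

```python
from mr2s import simulate, MRModel

# a synthetic study with known truth: 204 ascertained instruments,
# true causal effect 0.12 on the log-odds scale (OR ~ 1.13)
cfg = simulate.SimulationConfig(seed=7)
exposure, outcome, truth = simulate.simulate_pair(cfg)

res = MRModel.from_summary_frames(exposure, outcome).fit(seed=7, simex_n_sim=500)
print(res.summary())
```

```
Two-sample Mendelian randomization
==================================================================
Instruments used: 198   mean F: 217.70
ORs are per unit of the deposited exposure beta (exposure measurement unit not standardized).

method                                 OR           95% CI        p
------------------------------------------------------------------
IVW (fixed effects)                 1.124   [1.102, 1.146]  8.2e-32
IVW (multiplicative random effects)  1.124   [1.102, 1.146]  1.1e-30
Weighted median                     1.142   [1.106, 1.179]  2.3e-16
MR-Egger                            1.142   [1.091, 1.195]  5.2e-08
MR-Egger (SIMEX)                    1.146   [1.095, 1.200]  2.3e-08
------------------------------------------------------------------
Cochran Q = 204.53 (p = 0.342)   Rucker Q' = 203.93 (p = 0.334)
I2_GX = 99.53%
Egger intercept = -0.0006528 (0.0008604), p = 0.449
MR-PRESSO global p = 0.355; outliers: none identified
Primary method: ivw
```

Reading the output: every estimator's OR confidence interval covers the
simulated truth exp(0.12) ≈ 1.13; of the 204 generated SNPs, 198 survive
harmonization (frequency-ambiguous palindromic SNPs are dropped); the
heterogeneity and pleiotropy tests are all null, as they should be for a
dataset generated without pleiotropy, so plain IVW is recommended as
primary. The OR-scale caveat is printed because summary statistics
rarely state the exposure's measurement unit.

The same analysis from the shell:

```bash
mr2s simulate --out sim/ --seed 7
mr2s run --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
         --out results/ --seed 7
```

which writes `instrument_table.tsv`, `harmonized.tsv` (the scatter-plot
table), `forest.tsv` (one row per estimator), `diagnostics.tsv` +
`diagnostics.json`, the resolved config and a run log. Real data run the
same way: point `--exposure`/`--outcome` at tab- or comma-delimited
summary files (gzip ok; column names configurable via a YAML config) and
optionally `--ld` at a 3-column `snp_a snp_b r2` table from your
reference panel.

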