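# Methods

## Scope and data model

The package estimates total, direct and mediated effects of an exposure on
an outcome from GWAS summary statistics in the two-sample setting: the
variant–exposure, variant–mediator and variant–outcome association estimates
come from separate (assumed non-overlapping) samples, and only per-variant
betas, standard errors, alleles, frequencies and p-values are ever needed.
Continuous traits are assumed to be analysed in SD units and binary traits
on the log-odds scale; causal estimates against a binary outcome are
log-odds ratios per 1-SD of exposure, exponentiated only at the reporting
layer.

All regressions consume a *harmonized panel*: an allele-aligned, complete-
case J×T matrix of betas and SEs. Harmonization is deliberately minimal,
matching the convention of the consortium analyses the package targets:
variants are matched by identifier, a swapped effect/other allele pair
negates the beta and reflects the frequency, palindromic (A/T, G/C) pairs
are treated identically with no frequency-based strand inference, and any
other allele mismatch drops the variant (counted and logged). Proxy
substitution is never attempted, and only variants present in every trait
of a given model enter that model's panel. The first-listed dataset defines
the reference orientation — this is a free choice with no effect on any
estimate (a global re-orientation negates betas jointly), so it is simply
documented rather than configurable.

## Instrument selection

Instruments are variants associated with the relevant trait at
P < 5×10⁻⁸, greedily clumped so all retained pairs have LD r² < 0.001:
repeatedly retain the remaining variant with the smallest p-value and
discard everything correlated with it at or above the threshold. Ties on p
are broken by lexicographic variant id so results are reproducible. For
multivariable models, variants significant for *any* trait in the model are
pooled and clumped on the minimum p-value across traits. LD is supplied as
an explicit correlation matrix; variants missing from it cannot be shown to
be independent and are dropped with a warning rather than assumed unlinked.

Variance explained by an instrument set is Σⱼ 2fⱼ(1−fⱼ)βⱼ², the
standardized-trait approximation (`method="eaf"`), with
Σⱼ zⱼ²/(zⱼ²+nⱼ−2) available as an alternative (`method="z2"`); the two
differ only by the implicit standardization of the trait.

## Univariable estimators

Let rⱼ = β̂_Yj/β̂_Xj with first-order SE se_Yj/|β̂_Xj| (uncertainty in the
denominator is neglected — for instruments at genome-wide significance the
second-order correction is below 2% of the SE and is intentionally
omitted).

- **IVW (main analysis).** Weighted regression of β̂_Y on β̂_X through the
  origin with weights 1/se_Yj². Heterogeneity is summarized by Cochran's Q
  and absorbed multiplicatively: SE_RE = SE_fixed · max(1, √(Q/(J−1))).
  The clamp at 1 means exactly proportional data report the fixed-effect
  SE. A single variant degenerates to the Wald ratio.
- **MR-Egger.** Same regression with a free intercept after re-orienting
  every variant so β̂_Xj > 0. The slope is the causal estimate; the
  intercept estimates the average directional pleiotropic effect, and its
  two-sided test (p > 0.05 read as no evidence of directional pleiotropy)
  is reported alongside. Random-effects scaling uses J−2 degrees of
  freedom. P-values are normal-theory by default (`pvalue_dist="t"`
  switches to t with J−2 df).
- **Weighted median.** Ratio estimates are sorted; with standardized
  inverse-variance weights wⱼ and sⱼ = Σ_{k≤j}w_k − wⱼ/2, the estimate is
  the linear interpolation of r against s at s = 0.5. The SE is the
  standard deviation of the estimator over parametric bootstrap resamples
  β̂* ~ N(β̂, se²) drawn for both exposure and outcome (default 1000
  replicates; the seed is a required input so runs are reproducible).
- **Contamination mixture.** Ratio estimates from valid instruments are
  modelled N(θ, seⱼ²), invalid ones N(0, seⱼ² + ψ²); each variant
  contributes the larger of the two log-densities and the resulting profile
  log-likelihood is maximized over a grid of candidate θ. The 95% CI is
  every grid value within χ²₁(0.95)/2 = 1.92 units of the maximum (it may
  be asymmetric; no SE is defined). Defaults: ψ = 1.5 × SD of the ratio
  estimates; grid of 500 points spanning the ratio range ± 3 pooled SEs. A
  maximum on the grid edge is a hard error (widen the grid); a confidence
  set reaching the edge is truncated with a warning, since with a diffuse
  invalid component the profile genuinely flattens far from the data. The
  p-value is a likelihood-ratio test against θ = 0.

All four estimators negate under a joint sign flip of the exposure betas;
for MR-Egger the intercept negates too, because the internal re-orientation
flips the outcome column.

## Multivariable MR and mediation

The direct effect of the exposure conditional on genetically predicted
mediators is the exposure coefficient from the weighted zero-intercept
regression of β̂_Y on [β̂_X, β̂_M₁, …], weights 1/se_Yj², fitted on a pooled
instrument set. SEs carry the multiplicative scaling max(1, √(RSS_w/(J−K))).
A predictor column that is identically zero carries no information; it is
reported as unidentified (coefficient 0, infinite SE) and the rest of the
model is fitted as the nested regression, so dropping a null mediator
reproduces the univariable estimate exactly. Genuinely collinear predictors
are a hard error naming the traits. A binary mediator (e.g. diabetes
liability) enters as log-odds with no transformation; because genetic
liability does not guarantee trait expression this can bias mediation
estimates, so the pipeline logs the caveat and additionally fits the joint
model excluding binary mediators as a sensitivity analysis.

Proportion mediated is PM = 1 − θ_D/θ_T on the log scale, with the
first-order (delta-method) SE of the ratio computed with the covariance
between θ_D and θ_T set to zero — that covariance is not identifiable from
summary data, and the zero-covariance form reproduces the published
worked-example intervals exactly. The SE is implemented as
√((se_D/θ_T)² + (θ_D·se_T/θ_T²)²), algebraically identical to the usual
|R|√((se_D/θ_D)²+(se_T/θ_T)²) but defined at θ_D = 0, where it correctly
gives PM = 1 with SE se_D/|θ_T|. Because the total and direct estimates
share outcome data and instruments, their true covariance is positive, so
ignoring it *over*states the variance of the ratio; measured coverage of
the mediation CI in simulation is accordingly above nominal. Proportions
and CIs are reported unbounded (negative values are meaningful evidence of
no mediation) and rounded to whole percent only in the report writer.
Printed odds-ratio results can be fed straight in: θ = ln(OR),
se = (ln hi − ln lo)/3.92.

Effects entering mediation arithmetic for a binary outcome are log-ORs;
the non-collapsibility of the odds ratio means the "proportion" is a
log-OR-scale contrast, not a collapsible risk decomposition. This matches
the source analyses and is documented rather than corrected.

## The synthetic generator

`simulate_mediation_gwas` emulates the consortium setting under a linear
structural model: X = Σαⱼgⱼ + ε; M_m = δ_m X + Σκ_mj gⱼ + ε;
Y = τ_D X + Σ_m τ_m M_m (+ γⱼ on a pleiotropic fraction of variants). True
total effect: τ_D + Σ δ_m τ_m; true proportion mediated: 1 − τ_D/total.
Variants are partitioned into an exposure-specific set (αⱼ ~ N(0, α_sd²))
and disjoint mediator-specific sets (κ ~ N(0, κ_sd²)) — mediators *must*
have genetic effects of their own, otherwise every variant–mediator
association is proportional to the variant–exposure association and the
multivariable design matrix is singular up to noise, leaving the direct
effect unidentifiable. This also makes pooled instrument selection
meaningful: mediator-specific variants enter multivariable models through
the pooled clump, exactly as a mediator's own GWAS hits do in practice.

True direct effects are propagated through a block-diagonal LD matrix
(blocks of `ld_block_size` at constant within-block r; default independent
variants) to marginal associations, and each trait's observed betas are
drawn independently as β̂ ~ N(β_marginal, se²) with
se = 1/√(2nf(1−f)) for a unit-variance trait — the idealized two-sample
design with zero between-trait estimation covariance, consistent with the
zero-covariance mediation SE. Binary outcomes are simulated directly on the
log-odds scale; the estimators only ever see betas and SEs.

Defaults (one simulated "study"): J = 200 variants, n = 200,000 per GWAS,
two quantitative mediators, MAF ~ U(0.1, 0.5), α_sd = κ_sd = 0.025
(consortium-scale per-allele effects, ~0.7 of significant hits at these
sample sizes), δ = (0.3, 0.25), τ_mediator = (0.5, 0.4), τ_D = 0.25 — true
total 0.5, true proportion mediated 0.5 — and 20% of variants carrying
balanced (null-centred, additive) pleiotropy of SD 0.01.
`pleiotropy_mode="null"` instead *replaces* the causal path for flagged
variants, producing the contamination-mixture model's invalid-instrument
scenario (ratio estimates centred on zero).

What the generator does **not** emulate: overlapping GWAS samples (real
UK Biobank-based traits share participants, inducing estimation covariance
the package assumes away), case–control ascertainment for binary traits,
realistic genome-wide LD, winner's-curse-free replication designs, and
trait-variance rescaling of SEs. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data complications.

## Calibration behaviour measured by the test suite

Two deliberate fidelity choices show up as mild miscalibration, reproduced
and quantified by the test suite rather than hidden:

- Instruments are selected in the same exposure sample used for estimation
  — as consortium analyses do. The resulting winner's curse inflates
  selected |β̂_X| and biases the total effect toward the null by roughly
  half a standard error at the default configuration, putting IVW coverage
  of the truth at ~89–92% across replicate seeds instead of 95%.
- The contamination mixture's null-centred invalid component absorbs valid
  instruments whose noisy ratio happens to fall near zero, biasing its
  point estimate slightly away from the null; its profile-likelihood CI
  covers the truth in ~88% of no-pleiotropy replicates.

MR-Egger and the weighted median are unaffected by either mechanism and
cover at or above nominal rates. The multivariable direct effect and the
mediation proportion cover at ≥95% (the zero-covariance SE is
conservative). Under 30% invalid instruments the contamination mixture is
less biased than IVW in essentially every replicate, which is the property
it exists for.

## Numerical choices and degenerate inputs

- Two-sided p-values are normal-theory throughout (95% bounds at 1.96);
  the Egger t-option is the only exception.
- Exactly proportional panels give Q = 0 and the random-effects scale
  clamps to 1.
- A zero exposure beta makes the ratio undefined and is a hard error
  naming the variant (upstream significance filtering makes this
  unreachable in the pipeline).
- Clumping determinism: stable sort on (p, variant id).
- Stored p-values inconsistent with beta/se by more than one order of
  magnitude are warnings, not errors — consortium files disagree through
  rounding. Missing p-values are recomputed from beta/se where needed.
- Duplicate variant ids in a file keep the first record with a warning.
- The TSV writer serializes floats with `repr`, so write→read→write is
  byte-identical; missing fields are `NA`.
- Pipeline runs are byte-identical for a fixed config and seed: the only
  randomness (weighted-median bootstrap) is seeded from the config, and
  report rendering uses fixed formats.

## Problem sizes used by the validation suite

The replicate studies run at the default configuration (J = 200,
n = 200,000, 100 seeds) for coverage and robustness checks, 500 replicates
of 50-variant panels for the Egger intercept type-I error, and 20–40-variant
fixtures for the 1e-10 oracle-equivalence checks; these sizes give
Monte-Carlo error comfortably below the margins being asserted while
keeping the suite quick to run.

## Known limitations

- No conditional instrument-strength statistic exists for two-sample
  multivariable MR; a marginal mean F per predictor is logged as a
  descriptive only, and weak-instrument bias in the multivariable fits is
  not assessed.
- No winner's-curse or regression-dilution correction (see above).
- Mediator–mediator causal structure is not modelled: single-mediator
  proportions are not constrained to sum to the joint proportion, and the
  comparison is logged descriptively, not asserted.
- Out of scope by design: proxy lookup, strand inference, positional
  (window-based) clumping, reference-panel LD estimation, MR-PRESSO/mode
  estimators, Steiger filtering, and counterfactual (product-of-
  coefficients) mediation.
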