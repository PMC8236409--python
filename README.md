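# mrmediation

Two-sample Mendelian randomization (MR) mediation analysis from GWAS summary
statistics.

## The problem

Observational associations between an exposure (say, body mass index) and a
disease outcome (say, coronary artery disease) are confounded. MR sidesteps
this by using genetic variants as instrumental variables: a variant robustly
associated with the exposure, and affecting the outcome only through it,
identifies the causal effect from summary-level GWAS association estimates
alone. *Mediation* MR goes one step further and asks how much of that causal
effect flows through intermediate risk factors (blood pressure, diabetes
liability, lipids, smoking), by contrasting the **total** effect with the
**direct** effect that remains after adjusting for genetically predicted
mediators.

`mrmediation` implements that full analysis for epidemiologists working with
summary statistics:

- reading, writing and allele-harmonizing GWAS summary tables (swapped
  effect/other alleles negate β and reflect the effect-allele frequency;
  palindromic variants are kept at face value; strands are never flipped),
  plus fixed-effects meta-analysis of strata;
- instrument selection by genome-wide significance filtering
  (P < 5×10⁻⁸) and greedy LD clumping to pairwise r² < 0.001, either per
  trait or pooled across the traits of a multivariable model on the minimum
  p-value;
- univariable MR by four estimators: random-effects inverse-variance
  weighted (IVW, the main analysis), MR-Egger with its directional-pleiotropy
  intercept test, the precision-weighted median with bootstrap SE, and the
  contamination-mixture model with profile-likelihood CI;
- multivariable MR (weighted zero-intercept regression of variant–outcome on
  variant–trait betas) for direct effects and two-exposure mutual adjustment;
- mediation arithmetic with propagation-of-error confidence intervals;
- a synthetic summary-data generator with known mediation structure, so the
  whole pipeline is testable end to end without any data download.

## The statistics in brief

With harmonized per-variant estimates β̂_Xj (exposure), β̂_Mj (mediators) and
β̂_Yj (outcome, log-odds for a binary trait):

- **IVW**: weighted regression of β̂_Y on β̂_X through the origin, weights
  1/se²(β̂_Y); multiplicative random-effects SE inflation by
  max(1, √(Q/(J−1))) with Cochran's Q.
- **Multivariable IVW**: β̂_Y regressed jointly on [β̂_X, β̂_M₁, …], intercept
  fixed to zero, same weighting; the exposure's coefficient is its direct
  effect θ_D.
- **Proportion mediated**: with total effect θ_T and direct effect θ_D on the
  log scale,

      PM = 1 − θ_D/θ_T,
      SE(PM) = |θ_D/θ_T| · √( (se_D/θ_D)² + (se_T/θ_T)² )

  with the covariance term set to zero; the 95% CI is PM ± 1.96·SE and is
  deliberately not truncated to [0, 1].

## Worked example

The published worked example: the odds ratio of coronary artery disease per
1-SD higher genetically predicted BMI is 1.49 (95% CI 1.39–1.60), attenuating
to 1.34 (1.24–1.45) after adjusting for genetically predicted systolic blood
pressure. What proportion of the effect does blood pressure mediate?

```sh
$ mrmediation mediate --total-or 1.49,1.39,1.60 --direct-or 1.34,1.24,1.45 --mediator sbp
mediator	proportion	se	ci_low	ci_high	percent	percent_ci
sbp	0.26608	0.119919	0.0310434	0.501117	27	(3, 50)
```

Read: 27% (95% CI 3% to 50%) of the BMI–CAD effect is mediated by systolic
blood pressure — the CI excludes zero, so there is evidence for a genuine
mediating role.

The same machinery runs on full summary tables. On a synthetic dataset with a
known true total effect of 0.5 (log-odds per SD):

```sh
$ mrmediation simulate --seed 7 --out-dir demo/
$ mrmediation mr --exposure demo/exposure.tsv --outcome demo/outcome.tsv --ld demo/ld_matrix.tsv
method	beta	se	ci_low	ci_high	pvalue	n_variants	or	or_low	or_high
ivw	0.511608	0.0185989	0.475155	0.548062	1.42806e-166	48	1.66797	1.60826	1.7299
contamination_mixture	0.527019	NA	0.499578	0.575804	7.79884e-49	48	1.69388	1.64803	1.77856
weighted_median	0.521781	0.0245056	0.47375	0.569811	1.3385e-100	48	1.68503	1.60601	1.76793
egger	0.508387	0.0571838	0.396308	0.620465	6.08956e-19	48	1.66261	1.48633	1.85979
```

All four estimators agree with each other and bracket the generating value;
the `or` columns are the same estimates exponentiated to the odds-ratio
scale. A YAML-configured `mrmediation run` executes the whole graph — total
effects, per-mediator and joint direct effects, the sensitivity joint model
excluding binary mediators, and the mediation table — deterministically for a
fixed seed (see `mrmediation run --help`).

## Layout

- `src/mrmediation/summary_data.py` — containers, TSV I/O, harmonization,
  panel alignment, strata meta-analysis
- `src/mrmediation/instruments.py` — significance filtering, LD clumping,
  variance explained
- `src/mrmediation/mr_estimators.py` — IVW, MR-Egger, weighted median,
  contamination mixture
- `src/mrmediation/mvmr.py` — multivariable MR, mutual adjustment
- `src/mrmediation/mediation.py` — proportion mediated and its CI
- `src/mrmediation/synthetic_data.py` — structural-model generator, fixtures
- `src/mrmediation/pipeline.py`, `cli.py` — orchestration and the
  `mrmediation` command

See `docs/methods.md` for the modelling assumptions, default parameters and
known limitations.
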