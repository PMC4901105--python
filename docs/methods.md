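# Methods

This note documents the models, numerical choices and limitations of the
package. It states nothing the test suite or `scripts/acceptance.py` do
not themselves compute.

## Synthetic cohort model

The generator emulates a population-based adult Chinese cohort so that
every downstream estimator can be validated against known truth.

**Genotypes.** Each variant is drawn independently as
g ~ Binomial(2, RAF) — Hardy–Weinberg proportions at the specified
risk-allele frequency. The default 52-variant panel uses the published
frequencies and population-scale per-allele ORs (roughly 1.0–1.3) from
the packaged summary table. Missingness is missing-completely-at-random
per SNP. There is **no linkage disequilibrium, population structure or
relatedness**: these are deliberate non-goals, so the generator cannot
probe LD-related failure modes (proxy-SNP attenuation, cross-ethnic LD
differences).

**Covariates.** Age ~ N(51.4, 10.7²); sex with 40.5% male; ten regional
centres, uniformly assigned, with centre log-odds effects drawn
N(0, 0.2²); adiposity (BMI, WC, WHR, PBF) as a per-sex multivariate
normal with means/SDs matching the emulated cohort (e.g. BMI 23.4 ± 3.2
in men, 23.8 ± 3.5 in women) and a plausible positive correlation
structure (BMI–WC 0.8 down to WHR–PBF 0.45). Real adiposity is skewed
and the real age distribution truncated at 30–79; the normal
approximations are adequate for testing estimators but not for
distributional tails.

**Disease.** logit P(case) = b0 + Σβⱼgⱼ + 0.04·(age−51.4) +
0.10·female + centre effect + 0.10·(BMI−23.6) +
γ·(BMI−23.6)·(allele count − expectation), where γ is the
`interaction_coef` (0 by default). The covariate effect sizes are chosen
as epidemiologically plausible defaults (ORs of ~1.04/year of age,
~1.10/BMI unit). The intercept b0 is solved by bisection so the mean of
P(case) over the simulated individuals equals the target prevalence
(default 7.6%) to within 10⁻⁴.

**Severity.** The latent severity is the linear predictor plus standard
logistic noise; a case is exactly severity > 0. This gives
extreme-phenotype sampling an explicit definition: "severe cases" are the
top (1−q) of cases by severity and "hypernormal controls" the bottom
(1−q) of controls. The glucose-screening recruitment of the real study is
not modelled quantitatively; this severity construction is a testable
stand-in, not a claim about the original sampling design.

**Discovery studies.** Case–control discovery replicates are drawn from
the exact genotype distributions implied by the single-SNP logistic model
at the design prevalence (multinomial sampling of genotype counts among
cases and controls), optionally with the severity cut-offs above, then
fitted by maximum likelihood on the collapsed 3×2 table. A replicate is
"selected" when its Wald p passes `alpha_select` — the winner's-curse
mechanism. The selected-z distribution is validated against the
truncated-normal closed form E[Z | Z > c] = μ + φ(c−μ)/(1−Φ(c−μ)).

## Quality control

Per-SNP: call rate ≥ 95% and 1-df χ² Hardy–Weinberg test at
p ≥ 1.3×10⁻⁴ (0.05/384, the panel-wide Bonferroni level of the emulated
genotyping array). Per-sample: call rate ≥ 98% and inbreeding coefficient
F = 1 − observed/expected heterozygosity within |robust z| < 5. The
"SD score" of F is not fully specified in the source description; this
package uses median and 1.4826·MAD as centre and scale, a recorded choice
rather than an assertion about the original. Sex mismatch is accepted as
an input flag (no intensity data in scope). With only 52 panel SNPs the
98% sample call-rate filter trips at two missing genotypes, so simulated
per-SNP missingness defaults low (0.2%).

Diabetes classification: self-report with onset < 30 years and current
insulin treatment is classed as type 1 and excluded; other self-reports
are prevalent cases; screen-detection requires random glucose
≥ 7.0 mmol/l after > 8 h fasting, random glucose ≥ 11.1 mmol/l under
< 8 h fasting, or fasting glucose ≥ 7.0 mmol/l. A fasting time of exactly
8 h satisfies neither random-glucose rule (the rules are strict
inequalities); this boundary case is documented and configurable.

## Association

Per-allele logistic regression with age, sex and centre indicators;
Wald SEs and CIs at z = 1.959964 (1.96 is not accurate enough when
comparing printed ORs at ±0.01). Covariate-free fits collapse to the 3×2
dosage-by-outcome count table and are solved by Newton iteration — the
same MLE at a fraction of the cost, used throughout the simulation loops
and checked against a grid-search oracle to 4 decimals. Separation and
non-convergence are flagged on the result rather than raised; no
penalised fallback is applied by default.

The directional concordance test is an **exact one-sided binomial tail**
P(X ≥ k | n, ½). The published concordance p-values equal the one-sided
tail even though the source describes its tests globally as two-sided;
this package matches the printed numbers and records the discrepancy.

Genomic inflation: λ_obs = median(χ²)/0.4549364 and
λ₁₀₀₀ = 1 + (λ_obs − 1)(1/n_cases + 1/n_controls)/(2/1000), computed with
raw case/control counts.

The permutation family-wise procedure permutes the phenotype, refits the
covariate-only null per permutation and uses Rao score z-statistics per
SNP (equivalent to the Wald z to first order, orders of magnitude
cheaper), referring observed |z| to the permutation distribution of the
maximum: p_adj = (1 + #{max ≥ |z_obs|})/(B + 1).

## Meta-analysis and shrinkage

Fixed-effect inverse-variance pooling only (no random-effects model, by
scope). SEs are recovered from printed CIs; since printed ORs are rounded
to 2 decimals, pooled values can only be reproduced to about ±0.01, which
is the tolerance used in the reproduction tests. Cochran's Q uses the
χ²_{k−1} reference with the Bonferroni heterogeneity threshold
0.05/(55·3) = 3.0×10⁻⁴ as the default screen.

Attenuation is the slope of y (population log-OR) on x (discovery
log-OR) through the origin with weights 1/se_y²; the reference-axis
uncertainty is deliberately ignored, matching the inverse-variance
weighted regression convention — a bivariate errors-in-variables
treatment is out of scope. No analytic winner's-curse correction
(conditional-likelihood deconvolution) is attempted: the module measures
attenuation, it does not correct it. The published 19%/22% reduction
figures depend on supplementary per-SNP external estimates that are not
in the main-text table, so they are treated as context; the package's
claim — validated by simulation — is that the estimator recovers known
attenuation (0.80 injected → 20% ± 2 recovered) and detects
selection-induced attenuation in ≥95% of replicates.

## Genetic risk scores

GRS = Σwᵢgᵢ with w the natural-log per-allele OR of a named scheme
(all 1 for the unweighted score). Rescaling multiplies by
(2M)/(2Σw) where M is the number of SNPs, reading "total number of risk
alleles" as the maximal count 2M — an interpretive choice that makes the
unweighted identity (rescaled score = allele count) exact. Rescaling is
linear, so z-statistics are invariant, which is tested.

Missing genotypes are imputed with the SNP's mean observed dosage within
the individual's centre, falling back to the overall mean with a warning.

Mechanism classification: a variant is beta-cell (BC) if any beta-cell
criterion holds (decreased HOMA-B, OGTT beta-cell index, beta-cell
cluster membership, monogenic-diabetes locus); else insulin-resistance
(IR) if any IR criterion holds (increased HOMA-IR, fasting insulin,
IR cluster, triacylglycerol/IR traits) **and** the locus does not act
primarily through obesity — the obesity criterion is implemented as an
exclusion, one of two defensible readings. BC takes precedence on
conflicting evidence; both choices are configurable. The packaged 25 BC
/ 7 IR split is an illustrative assignment from standard locus biology
(the original evidence table is supplementary material); subscore
membership is config input, not a reproduction claim.

Variance explained uses the plug-in
PVE = 2β²p(1−p)/(2β²p(1−p) + se²·2n·p(1−p)).

Quartiles use sample quantiles with boundary ties assigned to the lower
quartile. Floating absolute risks assign every quartile (reference
included) a floated variance minimising the summed squared relative
error of all pairwise contrast variances (quasi-variances, positive by a
log parameterisation; exact for two levels; within 5% on simulated
4-level factors against the fitted covariance).

## Discrimination

C = P(score_case > score_control) + ½P(tie) by the midrank formula;
ties count ½ (a documented choice — the convention is not stated in the
source). Variances and the paired test use the DeLong structural
components, checked to 10 decimals against full pair enumeration.
Cross-validation forms k folds by seeded permutation; the original
"1000-fold / leave 0.1% out" design corresponds to k = n/(0.001·n)
= 1000, parameterised so tests run at k = 5–10. Per fold, cohort per-SNP
estimates are refitted on the complement, pooled with external estimates
by inverse variance, and applied only to the held-out fold. Whether the
baseline discrimination model includes covariates alongside the score is
configurable (`use_covariates`), as either reading is defensible.

## Strata and interaction

BMI classes use the WHO Asian cut-points (23, 27.5), value-equals-cut
going to the upper class so that "normal < 23" holds; WC/WHR/PBF use
sex-specific tertiles with boundary ties to the lower tertile.
Interaction is tested primarily with the continuous adiposity variable
(main effects centred to avoid near-collinearity of the product column)
and secondarily with ordinal stratum coding; the original computation
basis is ambiguous, so both are available and neither is asserted as the
original. The test suite also verifies the collider caveat: when the
score raises both adiposity and disease with no true interaction,
stratified analyses show apparent heterogeneity (the bounded middle
stratum attenuates relative to the open-ended tails).

## Problem sizes and numerical conventions

Simulation studies run at sizes chosen to give decisive Monte-Carlo
evidence on a desktop: estimator calibration at 200 replicates of
20,000 × 20; winner's curse at 200 replicates of 50 SNPs
(5,000/5,000 discovery, 20,000-person cohort re-estimation); null
calibration at 2,000 replicates of reduced n (per-SNP n = 1,000,
interaction n = 400, permutation n = 200 with B = 100). Intercept
bisection tolerance is 10⁻⁴ in prevalence; Newton/IRLS convergence
10⁻⁹–10⁻¹⁰ in the step; all randomness flows from
`numpy.random.default_rng` seeded once per entry point.

## Known limitations

- No LD, population structure, relatedness or X-chromosome handling.
- The synthetic cohort's covariate–disease effects are plausible
  defaults, not fitted to data; passing tests demonstrate estimator
  correctness under the generating model, not robustness to real-data
  violations (measurement error, non-normal adiposity, informative
  missingness).
- CI-rounding of printed inputs bounds printed-table reproduction at
  about ±0.01 on the OR scale.
- The permutation procedure assumes exchangeability of phenotypes given
  covariates, which the null refit only approximates under strong
  covariate effects.
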