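# t2dgrs

Population-based evaluation of type 2 diabetes risk variants: a tested
genetic-epidemiology pipeline for per-SNP association, cross-study
meta-analysis, winner's-curse/spectrum-bias quantification, weighted
genetic risk scores, risk discrimination and gene–adiposity interaction.

## The problem

Effect sizes of GWAS-discovered risk variants are usually estimated in
highly selected case–control samples. Two biases inflate them relative to
their population-level values: the **winner's curse** (estimates
conditioned on passing a significance threshold are biased upward,
especially at low power) and **spectrum bias** (sampling clear-cut cases
and hypernormal controls exaggerates contrasts). Population-based cohorts
give unbiased re-estimates, which matter for risk prediction: a genetic
risk score (GRS) weighted by biased effect estimates discriminates worse
than one weighted by population-scale estimates.

This package implements the full analysis stack for such a re-evaluation
— and, because individual-level biobank data are access-controlled, a
synthetic cohort generator with known ground truth against which every
stage is tested. It ships a transcription of published summary statistics
for 56 established type 2 diabetes variants (risk-allele frequencies,
per-allele ORs with 95% CIs from a Chinese population-based cohort and an
East Asian case–control consortium, and the published pooled values),
used both as reference inputs and as a reproduction target.

## Methods at a glance

- **Association**: per-allele logistic regression of case status on
  risk-allele dosage g ∈ {0,1,2}, adjusted for age, sex and regional
  centre; Wald CIs with z = 1.959964. Multiplicity by Holm, Benjamini–
  Hochberg, or a permutation max-|z| family-wise procedure.
- **Meta-analysis**: fixed-effect inverse-variance pooling,
  β̂ = Σwᵢβᵢ/Σwᵢ with wᵢ = 1/seᵢ²; SEs recovered from printed CIs as
  (ln hi − ln lo)/(2·1.959964); Cochran's Q heterogeneity.
- **Shrinkage**: weighted least-squares regression through the origin of
  population log-ORs on discovery log-ORs; proportional reduction
  1 − slope.
- **GRS**: weighted allele-dosage sums rescaled as
  GRS′ = GRS·(2M)/(2Σw), so one point ≈ one risk allele; centre-mean
  imputation of missing genotypes; beta-cell and insulin-resistance
  subscores; quartile gradients with floating absolute risks
  (quasi-variances).
- **Discrimination**: C-statistic with DeLong variance; paired DeLong
  test of weighting schemes; leave-fraction-out cross-validation of
  internally derived weights.
- **Interaction**: WHO Asian BMI classes and sex-specific tertiles of
  WC/WHR/PBF; stratified score associations and a score × adiposity
  product-term test.

## Worked example

```python
import numpy as np
from t2dgrs import (SimConfig, simulate_cohort, se_from_ci,
                    ivw_fixed_meta, StudyEstimate)
from t2dgrs import panel

# pool the published two-study estimates for KCNQ1 rs2237892
row = panel.load_panel().set_index("snp_id").loc["rs2237892"]
ests = [StudyEstimate("ckb", "rs2237892",
                      *se_from_ci(row.or_ckb, row.lo_ckb, row.hi_ckb)),
        StudyEstimate("agen", "rs2237892",
                      *se_from_ci(row.or_agen, row.lo_agen, row.hi_agen))]
print(round(ivw_fixed_meta(ests).or_, 2))   # 1.22

# a synthetic cohort at the study conditions
specs = panel.default_snp_specs("grs")      # 52 variants, published RAFs
cohort = simulate_cohort(SimConfig(n_individuals=20_000, snps=specs, seed=1))
print(round(100 * cohort.y.mean(), 1))      # 7.5  (% diabetes, target 7.6)
```

The numbered scripts under `analysis/` run the full narrative on the
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py     # cohort, 7.5% prevalence
python analysis/04_meta_analysis.py       # max |pooled OR - published| = 0.009
python analysis/05_winners_curse.py       # mean slope 0.87; slope<1 in 99% of reps
python analysis/06_risk_scores.py         # weighted C 0.580, Q4 vs Q1 OR 2.0
python analysis/07_adiposity_interaction.py
```

`analysis/05_winners_curse.py`, for example, prints the through-origin
regression slope of population re-estimates on genome-wide-significant
discovery estimates (its mean of ~0.87 is the winner's-curse attenuation;
a slope of 1 would mean no bias) and shows that an injected multiplicative
attenuation of 0.80 is recovered as a ~20% proportional reduction.

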