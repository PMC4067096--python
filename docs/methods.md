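# Methods

## Allele scores

Each score is an unweighted sum of expected risk-allele counts over its SNP
set.  Dosages arrive as expected counts in [0, 2] of some *counted* allele
per column; orientation re-expresses them as risk-allele counts
(`d -> 2 - d` when the column counts the other allele) per (score, SNP)
pair, because a SNP can carry different risk alleles in different scores
(TYR rs1042602: A for skin colour, C for freckling).  Children missing any
constituent dosage are excluded from that score — no imputation — so each
score has its own analysis N.  Strand-ambiguous (A/T, G/C) pairs cannot be
resolved from allele labels alone; the loader warns and trusts the stated
alleles, which the packaged definition table fixes.

Per-SNP QC reports minor-allele frequency (mean dosage / 2, folded), call
rate, and a 1-df chi-square Hardy-Weinberg test with the allele frequency
estimated from the sample.  HWE is tested on best-guess genotypes (dosages
rounded to the nearest integer): the conventional choice for imputed data,
since fractional dosages have no genotype counts.  Default exclusion
thresholds: MAF < 0.01, call rate < 0.95, HWE p < 5e-7.  The report is
advisory; the pipeline drops failing SNPs by default (configurable).

Inter-score correlations are computed residualize-then-correlate: each
score is residualized on the ancestry PCs by OLS over the common complete
cases, and squared Pearson correlations of the residuals are tabulated.

## Cosinor model

A single annual harmonic is the default: OLS of total 25(OH)D on
`[1, cos(2πt/T), sin(2πt/T)]`, T = 365.25 days, with t in days since
January 1 of the earliest draw year.  The epoch choice only rotates the
coefficient pair; amplitude, mesor and residuals are epoch-invariant
(tested).  Extra harmonics are available through `harmonics=` for data
with sharper seasonal shapes.  Residuals are recentred by adding back the
mesor so downstream effects stay in nmol/l; raw (mean-zero) residuals are
available with `recenter=False`.  Degenerate inputs fail loudly: identical
draw dates raise a rank-deficiency error, non-positive periods a
validation error.  Children sampled at several clinic visits contribute
one measure chosen by assessment priority (age 9, else 11, else 7).

## Association suite

Complete-case analysis throughout; every fit drops rows with any missing
value among its own variables and reports the N used.  The standard
adjustment set is age at the relevant assessment, sex, and PC1-PC10.
Model fitting is delegated to statsmodels (OLS, Logit); Wald 95% CIs;
logistic effects on the log-odds scale with an odds-ratio column by
exponentiation.  t-tests default to the Welch (unequal-variance) form;
the pooled form is available.  The likelihood-ratio interaction test fits
nested models on identical rows and refers `2(l_full - l_reduced)` to a
1-df chi-square; an identically zero product column short-circuits to
statistic 0, p 1.  The squared semipartial correlation is the R-squared
increment when the exposure joins the covariates, computed on the same
rows for both fits; a collinear exposure contributes exactly 0, while a
rank-deficient reduced model is an error.  Nominal p-values are reported
without multiplicity adjustment, matching the analysis design.

Derived variables: combined freckles is 1 if a freckle was seen at either
exam age, 0 if both exams were negative, inherits a valid later response
when the earlier one is missing, and is missing when a negative earlier
exam has no later follow-up.  Combined sunburn over six questionnaire
sweeps is 1 on any report, 0 only when all six are negative, missing
otherwise.  Mole counts are grouped in sample quartiles with ties assigned
to the lower bin (recorded in the output metadata); the age-15 total mole
count is the sum over arms and legs.

## Synthetic cohort generator

The generator emulates the study's data structure with known truth so the
pipeline can be validated by parameter recovery.

**Genotypes.** Independent SNPs (linkage equilibrium) in Hardy-Weinberg
proportions at CEU-like counted-allele frequencies.  The packaged
frequencies are placeholders — the source cohort's frequencies are not
public — chosen so simulated score means and SDs approximate the published
descriptive statistics; under LE the inter-score R² values (0.23 / 0.17 /
0.08) differ somewhat from the published 0.19 / 0.22 / 0.01, which real
shared LD would modify.  Optional Gaussian blur maps hard calls to
imputation-like dosages.

**Effects.** The calibration file stores published *marginal* per-score
effects (single-exposure adjusted models).  Because the scores share SNPs,
the generator solves direct effects `b = Σ⁻¹ diag(Σ) m` from the analytic
LE score covariance Σ (per shared SNP: `±2p(1-p)`, negative when the two
scores' risk alleles disagree), so that single-score regressions on
simulated cohorts recover the stated marginals.  Defaults: 0.6 / 0.3 / 0.4
nmol/l per unit on habitual 25(OH)D, 0.41 / 0.18 / 0.22 reflectance units
per unit, sex difference −3.41 nmol/l (girls − boys), −0.8 nmol/l per
maternal-education level.

**Reflectance variance.** The total reflectance variance is fixed by the
published pair (effect 0.41, unique variance share 3.46%):
`var = 0.41² · var(SCS) / 0.0346 ≈ 9.5`, with the residual SD derived
after subtracting the systematic terms.

**Serum.** `total = 63 + season(t) + centred effects + gamma noise`, with
draw dates uniform over a 24-month window (sinusoid identifiable), seasonal
amplitude 12 nmol/l peaking around day 196 (a ~24 nmol/l winter-summer
swing, typical for UK children), and the noise gamma *cumulant-matched*:
its variance and third central moment are set so the marginal total matches
the configured gamma family (mean 63, SD 19 nmol/l) in mean, variance and
skewness after accounting for the systematic terms.  A normal marginal
with these moments would put ~2.3% of children below the 25 nmol/l
deficiency threshold; the matched right-skewed marginal puts ~0.5% there,
as observed.  D2 is a small positive component (a few nmol/l) with
D3 = total − D2.

**Covariates and confounding.** Sex Bernoulli(0.5); three maternal-
education levels (0.3/0.4/0.3); assessment ages around 49, 61 and 186
months, serum draws mixing the 9-, 11- and 7-year visits (0.68/0.155/
0.165).  PCs are standard normal; with `pc_allele_shift > 0` PC1 shifts
every counted-allele frequency and enters the serum and reflectance
means, creating genuine population-stratification confounding: omitting
the PCs biases score effects, including PC1-PC10 removes the bias exactly
(partialling PC1 cancels the induced covariance — demonstrated in the
tests).  The default shift (0.01) is small, consistent with adjustment
changing published estimates only marginally.

**Missingness** is MCAR at rates reproducing the published analysis Ns on
a serum cohort of N = 5649: reflectance and its exam age share one
clinic-visit mask (~950 observed), freckle and early mole exams ~13%
observed, the age-15 mole count ~49%, tanning category ~70%, each sunburn
sweep 95%.  Real attrition is not MCAR; recovery results show estimator
correctness under the missingness pattern, not robustness to informative
dropout.

**Determinism.** One seed; `SeedSequence.spawn` gives one stream per stage
(PCs, genotypes, phenotypes, serum, missingness) in fixed order, so
cohorts are bit-reproducible.

## Validation strategy and problem sizes

Oracle suites check each statistic against an independent route: HWE
against an exhaustive enumeration of all genotype configurations with
total ≤ 30 via scipy's chi-square; OLS against the closed-form
normal-equations solution on random small instances; the semipartial
against an explicit two-model statsmodels difference; the cosinor against
noiseless closed-form inversion and residual orthogonality; the LRT
against its nominal 5% null rejection rate (2000 replicates at n = 1000).
End-to-end recovery runs 200 calibrated cohorts of N = 5649 (about half a
minute in total) and requires every injected effect's mean estimate to lie
within two Monte-Carlo standard errors of its calibrated value; the
semipartial share is allowed its ~1/n small-sample upward bias at n ≈ 950.
Null calibration pools adjusted-model p-values across ~220 zero-effect
cohorts and tests uniformity by Kolmogorov-Smirnov.

## Known limitations

- Linkage equilibrium across SNPs; no LD or haplotype structure.
- MCAR missingness only.
- The cosinor assumes a stable annual rhythm; no age or latitude terms
  (the config exposes extra harmonics but not covariate-dependent
  seasonality).
- Allele frequencies are CEU-like placeholders, clearly labelled.
- The generator's behavioural variables (sun block, clothing, SPF) have
  plausible but uncalibrated effect sizes; they exercise the logistic
  models rather than reproduce published associations.
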