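# Cohort-calibrated effect configuration for the synthetic generator.
#
# The `marginal` blocks state published single-exposure (adjusted) effect
# estimates; the generator solves the direct per-score effects so that
# single-score adjusted regressions on simulated cohorts recover these
# marginals despite the scores being correlated (shared SNPs).
# Units: nmol/l per score unit for 25(OH)D, reflectance units per score
# unit for reflectance.  Users may copy and edit this file and pass it to
# `load_calibration`.

cohort:
  n: 5649

vitd:
  marginal_mean: 63.0          # nmol/l, marginal of total 25(OH)D
  marginal_sd: 19.0            # nmol/l
  season_amplitude: 12.0       # nmol/l, annual harmonic half-swing
  season_peak_day: 196         # day of year (mid July)
  marginal_effects:            # per-unit score effects on habitual 25(OH)D
    skin_colour: 0.6
    tanning: 0.3
    freckling: 0.4
  sex_effect: -3.41            # girls minus boys, nmol/l
  education_effect: -0.8       # per maternal-education level (0/1/2)

reflectance:
  baseline: 65.0               # EEL reflectance units, population mean
  marginal_effects:
    skin_colour: 0.41
    tanning: 0.18
    freckling: 0.22
  semipartial_r2_skin_colour: 0.0346   # share of reflectance variance unique
                                       # to the skin colour score; fixes the
                                       # total reflectance variance
  sex_effect: -0.30            # girls slightly darker

# Risk-allele frequencies of the generator's counted allele per SNP.
# CEU-like placeholders (the source cohort's frequencies are not public),
# chosen so simulated score means/SDs approximate the published
# descriptive statistics.
allele_freqs:
  rs12203592: 0.08
  rs1042602: 0.40
  rs12913832: 0.78
  rs1805007: 0.08
  rs4911414: 0.35
  rs1015362: 0.75
  rs32579: 0.60
  rs12210050: 0.20
  rs1393350: 0.25
  rs7969151: 0.30
  rs17094273: 0.20
  rs154659: 0.40
  rs11648785: 0.60
  rs7279297: 0.70
  rs2153271: 0.60
  rs619865: 0.15

# Tanning-ability category proportions (from lowest to highest latent
# burning tendency), matching the published category counts.
tanning_categories:
  always_tans_never_burns: 0.2332
  tans_easily_rarely_burns: 0.5576
  doesnt_change: 0.0593
  burns_easily_rarely_tans: 0.1381
  always_burns_never_tans: 0.0119

# Fraction of the cohort with each variable unobserved (MCAR).  The skin
# exam variables reflect the small clinic subsample; serum is always
# present because the simulated cohort is the serum sample.
missingness:
  reflectance: 0.832
  freckles: 0.87
  moles_early: 0.87
  moles_186m: 0.5125
  tanning_category: 0.2986
  sunburn_sweep: 0.05
  maternal_education: 0.05

confounding:
  pc_allele_shift: 0.01        # risk-allele frequency shift per SD of PC1
  pc_vitd_effect: 0.5          # nmol/l per SD of PC1 on habitual 25(OH)D
  pc_reflectance_effect: 0.1   # reflectance units per SD of PC1
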