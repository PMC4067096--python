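"""Synthetic cohort generator with known ground truth.

Generates cohorts that emulate the structure of the study data so every
pipeline stage can be validated by parameter recovery:

* genotypes drawn under Hardy-Weinberg equilibrium at CEU-like risk-allele
  frequencies, independent across SNPs (linkage equilibrium);
* pigmentation phenotypes and sun behaviours driven by the true genetic
  scores through linear / logistic / ordered-threshold links;
* serum 25(OH)D with an annual sinusoid against draw date, linear score /
  sex / maternal-education effects, and a right-skewed individual noise
  term chosen so the *marginal* of total 25(OH)D matches the configured
  gamma family (mean 63, SD 19 nmol/l by default) in its first three
  cumulants;
* optional population-stratification confounding: the first principal
  component shifts allele frequencies and enters the outcomes, so omitting
  the PCs biases effect estimates while including them removes the bias.

The packaged calibration (``data/calibration.yaml``) stores the published
*marginal* per-score effects.  Because the scores share SNPs, the generator
converts them to direct effects b = Sigma^-1 diag(Sigma) m using the
analytic linkage-equilibrium score covariance Sigma, so that single-score
adjusted regressions on simulated cohorts recover the stated marginals.

All randomness flows from a single seed via ``numpy.random.SeedSequence``:
``simulate_cohort`` spawns one child stream per stage (principal
components, genotypes, phenotypes, serum, missingness), in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .scores import DosageMatrix, ScoreDefinition, load_score_definitions

__all__ = [
    "GeneratorConfig",
    "EffectSpec",
    "load_calibration",
    "default_config",
    "expected_score_covariance",
    "solve_direct_effects",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_serum",
    "simulate_cohort",
    "SimulatedCohort",
]


def _packaged_calibration() -> dict:
    ref = resources.files("pigmentscore.data") / "calibration.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_CAL = _packaged_calibration()


@dataclass
class EffectSpec:
    """Per (exposure, outcome) effect calibration.

    ``vitd_marginal`` and ``reflectance_marginal`` are *marginal* per-unit
    score effects (single-exposure adjusted models); the generator converts
    them to direct effects internally.  Logistic effects are log-odds per
    score unit on the centred score.
    """

    vitd_marginal: dict = field(default_factory=lambda: dict(_CAL["vitd"]["marginal_effects"]))
    reflectance_marginal: dict = field(
        default_factory=lambda: dict(_CAL["reflectance"]["marginal_effects"])
    )
    sex_vitd: float = _CAL["vitd"]["sex_effect"]
    education_vitd: float = _CAL["vitd"]["education_effect"]
    sex_reflectance: float = _CAL["reflectance"]["sex_effect"]
    reflectance_semipartial_target: float = _CAL["reflectance"]["semipartial_r2_skin_colour"]
    reflectance_noise_sd: float | None = None  # derived from the target when None
    freckles_logodds: float = 0.45        # per freckling-score unit
    freckles_prevalence: float = 0.41
    burn_sweep_logodds: float = 0.15      # per tanning-score unit, per sweep
    burn_sweep_prevalence: float = 0.0265
    sunblock_logodds: float = 0.20        # per skin-colour unit
    sunblock_sex_logodds: float = 0.30    # girls use sun block more
    clothing_logodds: float = 0.15
    spf_high_logodds: float = 0.15
    mole_log_effect: float = 0.03         # log-mean mole count per tanning unit
    tanning_latent_sd: float = 3.0


@dataclass
class GeneratorConfig:
    """Study-condition defaults for one simulated cohort."""

    n: int = _CAL["cohort"]["n"]
    allele_freqs: dict = field(default_factory=lambda: dict(_CAL["allele_freqs"]))
    effects: EffectSpec = field(default_factory=EffectSpec)
    vitd_mean: float = _CAL["vitd"]["marginal_mean"]
    vitd_sd: float = _CAL["vitd"]["marginal_sd"]
    season_amplitude: float = _CAL["vitd"]["season_amplitude"]
    season_peak_day: float = _CAL["vitd"]["season_peak_day"]
    period: float = 365.25
    draw_start: str = "2002-01-01"
    draw_window_days: int = 730           # 24 months: sinusoid identifiable
    reflectance_baseline: float = _CAL["reflectance"]["baseline"]
    tanning_categories: dict = field(default_factory=lambda: dict(_CAL["tanning_categories"]))
    missingness: dict = field(default_factory=lambda: dict(_CAL["missingness"]))
    pc_allele_shift: float = _CAL["confounding"]["pc_allele_shift"]
    pc_vitd_effect: float = _CAL["confounding"]["pc_vitd_effect"]
    pc_reflectance_effect: float = _CAL["confounding"]["pc_reflectance_effect"]
    dosage_noise_sd: float = 0.0
    n_pcs: int = 10

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be at least 1")
        if self.vitd_sd <= 0:
            raise ValidationError("vitd_sd must be positive")
        for rsid, p in self.allele_freqs.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"{rsid}: allele frequency {p} outside [0, 1]")


def load_calibration(path=None) -> GeneratorConfig:
    """GeneratorConfig from a calibration YAML (packaged file by default)."""
    if path is None:
        return GeneratorConfig()
    with open(path) as fh:
        cal = yaml.safe_load(fh)
    effects = EffectSpec(
        vitd_marginal=dict(cal["vitd"]["marginal_effects"]),
        reflectance_marginal=dict(cal["reflectance"]["marginal_effects"]),
        sex_vitd=cal["vitd"]["sex_effect"],
        education_vitd=cal["vitd"]["education_effect"],
        sex_reflectance=cal["reflectance"]["sex_effect"],
        reflectance_semipartial_target=cal["reflectance"]["semipartial_r2_skin_colour"],
    )
    return GeneratorConfig(
        n=cal["cohort"]["n"],
        allele_freqs=dict(cal["allele_freqs"]),
        effects=effects,
        vitd_mean=cal["vitd"]["marginal_mean"],
        vitd_sd=cal["vitd"]["marginal_sd"],
        season_amplitude=cal["vitd"]["season_amplitude"],
        season_peak_day=cal["vitd"]["season_peak_day"],
        tanning_categories=dict(cal["tanning_categories"]),
        missingness=dict(cal["missingness"]),
        pc_allele_shift=cal["confounding"]["pc_allele_shift"],
        pc_vitd_effect=cal["confounding"]["pc_vitd_effect"],
        pc_reflectance_effect=cal["confounding"]["pc_reflectance_effect"],
    )


def default_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


# ---------------------------------------------------------------------------
# Analytic score covariance and effect solving
# ---------------------------------------------------------------------------

def generator_counted_alleles(definitions: Sequence[ScoreDefinition]) -> dict[str, str]:
    """The allele the generator counts per SNP.

    Convention: the risk allele of the *first* score listing the SNP (a SNP
    can carry different risk alleles per score); `orient_dosages` flips for
    the other scores.
    """
    counted: dict[str, str] = {}
    for definition in definitions:
        for snp in definition.snps:
            counted.setdefault(snp.rsid, snp.risk_allele)
    return counted


def expected_score_covariance(
    definitions: Sequence[ScoreDefinition],
    allele_freqs: Mapping[str, float],
) -> pd.DataFrame:
    """Closed-form score covariance under linkage equilibrium and HWE.

    For a shared SNP with counted-allele frequency p, the per-SNP dosage
    variance is 2p(1-p); the contribution to Cov(score_a, score_b) carries
    sign -1 when the two scores' risk alleles for that SNP disagree.
    """
    counted = generator_counted_alleles(definitions)
    names = [d.name for d in definitions]
    sigma = pd.DataFrame(0.0, index=names, columns=names)
    for a in definitions:
        for b in definitions:
            cov = 0.0
            shared = set(a.rsids) & set(b.rsids)
            for rsid in shared:
                p = allele_freqs[rsid]
                sa = 1.0 if a.snp(rsid).risk_allele == counted[rsid] else -1.0
                sb = 1.0 if b.snp(rsid).risk_allele == counted[rsid] else -1.0
                cov += sa * sb * 2 * p * (1 - p)
            sigma.loc[a.name, b.name] = cov
    return sigma


def solve_direct_effects(sigma: pd.DataFrame, marginals: Mapping[str, float]) -> pd.Series:
    """Direct per-score effects realizing the stated marginal effects.

    A single-score regression estimates m_j = (Sigma b)_j / Sigma_jj, so
    b = Sigma^-1 diag(Sigma) m.
    """
    names = list(sigma.index)
    m = np.array([marginals[n] for n in names], dtype=float)
    d = np.diag(np.diag(sigma.to_numpy()))
    b = np.linalg.solve(sigma.to_numpy(), d @ m)
    return pd.Series(b, index=names)


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: GeneratorConfig,
    rng: np.random.Generator,
    definitions: Sequence[ScoreDefinition] | None = None,
    pc1: np.ndarray | None = None,
) -> DosageMatrix:
    """HWE genotypes at the configured frequencies, independent across SNPs.

    With ``pc1`` given and ``pc_allele_shift`` > 0, each individual's
    counted-allele frequency is shifted by ``pc_allele_shift * pc1``
    (clipped to (0.02, 0.98)), linking the scores to ancestry structure.
    Optional ``dosage_noise_sd`` blurs hard calls into expected dosages,
    clipped to [0, 2], emulating imputation output.
    """
    if definitions is None:
        definitions = load_score_definitions()
    counted = generator_counted_alleles(definitions)
    n = config.n
    individuals = pd.Index([f"ind{i:05d}" for i in range(n)], name="individual")
    columns = {}
    for rsid, allele in counted.items():
        p = config.allele_freqs[rsid]
        if pc1 is not None and config.pc_allele_shift:
            p_i = np.clip(p + config.pc_allele_shift * pc1, 0.02, 0.98)
        else:
            p_i = np.full(n, p)
        geno = rng.binomial(2, p_i).astype(float)
        if config.dosage_noise_sd > 0:
            geno = np.clip(geno + rng.normal(0, config.dosage_noise_sd, n), 0.0, 2.0)
        columns[rsid] = geno
    frame = pd.DataFrame(columns, index=individuals)
    return DosageMatrix(frame, counted)


def _true_scores(
    dosages: DosageMatrix, definitions: Sequence[ScoreDefinition]
) -> pd.DataFrame:
    """Ground-truth scores summed directly from the generator's dosages."""
    out = {}
    for definition in definitions:
        total = np.zeros(len(dosages.individuals))
        for snp in definition.snps:
            col = dosages.dosages[snp.rsid].to_numpy()
            if dosages.counted_allele[snp.rsid] == snp.risk_allele:
                total += col
            else:
                total += 2.0 - col
        out[definition.name] = total
    return pd.DataFrame(out, index=dosages.individuals)


def _logistic_prob(prevalence: float, slope: float, x_centred: np.ndarray) -> np.ndarray:
    intercept = np.log(prevalence / (1 - prevalence))
    return 1.0 / (1.0 + np.exp(-(intercept + slope * x_centred)))


def simulate_phenotypes(
    dosages: DosageMatrix,
    config: GeneratorConfig,
    rng: np.random.Generator,
    definitions: Sequence[ScoreDefinition] | None = None,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Phenotypes, behaviours and covariates driven by the true scores.

    Returns a cohort table (without serum columns): sex, maternal education,
    assessment ages, PCs, skin reflectance, tanning-ability category,
    freckle observations at 49/61 months, sunburn reports over six sweeps,
    mole counts, and sun-behaviour binaries.  Missingness is *not* applied
    here; `simulate_cohort` applies it after the serum stage.
    """
    if definitions is None:
        definitions = load_score_definitions()
    eff = config.effects
    n = len(dosages.individuals)
    idx = dosages.individuals
    truth = _true_scores(dosages, definitions)
    names = list(truth.columns)
    centred = truth - truth.mean()

    if pcs is None:
        pcs = pd.DataFrame(
            rng.normal(size=(n, config.n_pcs)),
            index=idx,
            columns=[f"pc{i}" for i in range(1, config.n_pcs + 1)],
        )

    sigma = expected_score_covariance(definitions, config.allele_freqs)
    b_refl = solve_direct_effects(sigma, eff.reflectance_marginal)

    sex = rng.binomial(1, 0.5, n).astype(float)          # 0 boys, 1 girls
    education = rng.choice(3, size=n, p=[0.3, 0.4, 0.3]).astype(float)

    cohort = pd.DataFrame(index=idx)
    cohort["sex"] = sex
    cohort["maternal_education"] = education
    cohort[pcs.columns] = pcs.to_numpy()
    cohort["age_reflectance_months"] = rng.normal(49.5, 1.0, n)
    cohort["age_49m_months"] = rng.normal(49.5, 1.0, n)
    cohort["age_61m_months"] = rng.normal(61.5, 1.0, n)
    cohort["age_186m_months"] = rng.normal(186.0, 2.0, n)

    # reflectance: total variance fixed by the published effect and unique
    # variance share of the skin colour score
    systematic = (
        centred.to_numpy() @ b_refl.to_numpy()
        + eff.sex_reflectance * (sex - 0.5)
        + config.pc_reflectance_effect * pcs["pc1"].to_numpy()
    )
    if eff.reflectance_noise_sd is not None:
        noise_var = eff.reflectance_noise_sd**2
    else:
        m_scs = eff.reflectance_marginal["skin_colour"]
        var_target = (
            m_scs**2 * sigma.loc["skin_colour", "skin_colour"]
            / eff.reflectance_semipartial_target
        )
        noise_var = var_target - systematic.var()
        if noise_var <= 0:
            raise ValidationError(
                "reflectance systematic variance exceeds the target variance"
            )
    cohort["reflectance"] = (
        config.reflectance_baseline + systematic + rng.normal(0, np.sqrt(noise_var), n)
    )

    # tanning-ability category via ordered thresholds on a latent variable
    latent = truth["tanning"].to_numpy() + rng.normal(0, eff.tanning_latent_sd, n)
    props = np.array(list(config.tanning_categories.values()))
    labels = list(config.tanning_categories.keys())
    cum = np.cumsum(props)[:-1]
    edges = np.quantile(latent, cum)
    cohort["tanning_category"] = pd.Categorical.from_codes(
        np.searchsorted(edges, latent, side="right"), categories=labels, ordered=True
    )

    # freckles: one underlying status observed at both exam ages
    p_fr = _logistic_prob(eff.freckles_prevalence, eff.freckles_logodds,
                          centred["freckling"].to_numpy())
    freckled = rng.binomial(1, p_fr).astype(float)
    cohort["freckles_49m"] = freckled
    cohort["freckles_61m"] = freckled

    # sunburn: six questionnaire sweeps, small per-sweep probability
    p_burn = _logistic_prob(eff.burn_sweep_prevalence, eff.burn_sweep_logodds,
                            centred["tanning"].to_numpy())
    for k, age in enumerate((54, 65, 69, 77, 103, 140)):
        cohort[f"sunburn_{age}m"] = rng.binomial(1, p_burn).astype(float)

    # moles: overdispersed counts (gamma-Poisson), log-linear in the score
    def nb_counts(mean, score_effect):
        mu = mean * np.exp(eff.mole_log_effect * score_effect)
        shape = 3.0  # overdispersion: var = mu + mu^2/shape
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam).astype(float)

    ts_c = centred["tanning"].to_numpy()
    cohort["mole_count_49m"] = nb_counts(11.0, ts_c)
    cohort["mole_count_61m"] = nb_counts(18.0, ts_c)
    cohort["mole_arms_186m"] = nb_counts(7.0, ts_c)
    cohort["mole_legs_186m"] = nb_counts(7.0, ts_c)

    # sun behaviours
    scs_c = centred["skin_colour"].to_numpy()
    sunblock_logit = (
        np.log(0.35 / 0.65)
        + eff.sunblock_logodds * scs_c
        + eff.sunblock_sex_logodds * (sex - 0.5)
    )
    cohort["sunblock_always"] = rng.binomial(
        1, 1.0 / (1.0 + np.exp(-sunblock_logit))
    ).astype(float)
    cohort["clothing_always"] = rng.binomial(
        1, _logistic_prob(0.20, eff.clothing_logodds, scs_c)
    ).astype(float)
    cohort["spf_25_plus"] = rng.binomial(
        1, _logistic_prob(0.30, eff.spf_high_logodds, scs_c)
    ).astype(float)
    cohort["time_sun_local"] = rng.binomial(1, 0.5, n).astype(float)
    cohort["time_sun_abroad"] = rng.binomial(1, 0.4, n).astype(float)

    return cohort


def simulate_serum(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Add draw dates, ages at draw and 25(OH)D columns to the cohort.

    total = marginal mean + seasonal sinusoid + centred score/sex/education/
    PC effects + gamma noise.  The noise gamma is cumulant-matched: its
    variance and third central moment are chosen so the marginal total
    matches the configured gamma family (``vitd_mean``, ``vitd_sd``) in
    mean, variance and skewness after accounting for the systematic terms.
    """
    eff = config.effects
    n = len(cohort)
    definitions = load_score_definitions()
    sigma = expected_score_covariance(definitions, config.allele_freqs)
    b_vd = solve_direct_effects(sigma, eff.vitd_marginal)

    # assessment mix: age ~9.9 y, samples from the 9-, 11- or 7-year visits
    assessment = rng.choice([9, 11, 7], size=n, p=[0.68, 0.155, 0.165])
    age_mean = pd.Series({9: 119.0, 11: 140.0, 7: 90.0})
    age = rng.normal(age_mean.reindex(assessment).to_numpy(), 3.0)
    age = np.clip(age, 85, 163)

    start = pd.Timestamp(config.draw_start)
    offsets = rng.uniform(0, config.draw_window_days, n)
    draw_dates = start + pd.to_timedelta(offsets, unit="D")
    doy = draw_dates.dayofyear.to_numpy().astype(float)
    season = config.season_amplitude * np.cos(
        2 * np.pi * (doy - config.season_peak_day) / config.period
    )

    centred = truth - truth.mean()
    systematic = (
        season
        + centred.to_numpy() @ b_vd.to_numpy()
        + eff.sex_vitd * (cohort["sex"].to_numpy() - 0.5)
        + eff.education_vitd * (cohort["maternal_education"].to_numpy() - 1.0)
        + config.pc_vitd_effect * cohort["pc1"].to_numpy()
    )
    systematic = systematic - systematic.mean()

    # cumulant matching against the target gamma marginal
    k_t = config.vitd_mean**2 / config.vitd_sd**2
    theta_t = config.vitd_sd**2 / config.vitd_mean
    m3_target = 2 * k_t * theta_t**3
    var_noise = config.vitd_sd**2 - systematic.var()
    if var_noise <= 0:
        raise ValidationError(
            "systematic 25(OH)D variance exceeds the configured marginal variance"
        )
    m3_sys = float(np.mean(systematic**3))
    m3_noise = m3_target - m3_sys
    if m3_noise <= 0:
        raise ValidationError("cannot match the configured skewness with a gamma noise term")
    theta_n = m3_noise / (2 * var_noise)
    k_n = var_noise / theta_n**2
    noise = rng.gamma(k_n, theta_n, n) - k_n * theta_n

    total = config.vitd_mean + systematic + noise
    if np.any(total <= 0):
        warnings.warn("clipping non-positive simulated 25(OH)D values", stacklevel=2)
        total = np.clip(total, 0.5, None)

    d2 = np.minimum(rng.gamma(4.0, 0.75, n), 0.3 * total)  # small D2 component
    out = cohort.copy()
    out["draw_date"] = draw_dates
    out["age_at_draw_months"] = age
    out["serum_assessment_years"] = assessment.astype(float)
    out["d2"] = d2
    out["d3"] = total - d2
    out["total_25ohd"] = total
    noise_params = {"gamma_shape": float(k_n), "gamma_scale": float(theta_n),
                    "noise_var": float(var_noise)}
    return out, noise_params


def _apply_missingness(
    cohort: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """MCAR missingness per the configured rates.

    The skin-exam variables (reflectance, freckles, early mole counts) are
    restricted to a clinic subsample; the questionnaire sweeps lose a small
    independent fraction each.
    """
    rates = config.missingness
    out = cohort.copy()
    n = len(out)

    def mask(rate):
        return rng.uniform(size=n) < rate

    # reflectance and its exam age are missing together (same clinic visit)
    skin_exam_missing = mask(rates.get("reflectance", 0.0))
    for column in ("reflectance", "age_reflectance_months"):
        out[column] = out[column].where(~skin_exam_missing)

    column_rates = {
        "freckles_49m": rates.get("freckles", 0.0),
        "freckles_61m": rates.get("freckles", 0.0),
        "mole_count_49m": rates.get("moles_early", 0.0),
        "mole_count_61m": rates.get("moles_early", 0.0),
        "mole_arms_186m": rates.get("moles_186m", 0.0),
        "mole_legs_186m": rates.get("moles_186m", 0.0),
        "tanning_category": rates.get("tanning_category", 0.0),
        "maternal_education": rates.get("maternal_education", 0.0),
    }
    for age in (54, 65, 69, 77, 103, 140):
        column_rates[f"sunburn_{age}m"] = rates.get("sunburn_sweep", 0.0)
    for column, rate in column_rates.items():
        if rate > 0 and column in out.columns:
            if isinstance(out[column].dtype, pd.CategoricalDtype):
                out.loc[mask(rate), column] = np.nan
            else:
                out[column] = out[column].where(~mask(rate))
    return out


@dataclass
class SimulatedCohort:
    """One generated cohort plus its ground truth."""

    dosages: DosageMatrix
    cohort: pd.DataFrame
    true_scores: pd.DataFrame
    direct_effects: dict
    config: GeneratorConfig
    seed: int
    noise_params: dict


def simulate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> SimulatedCohort:
    """Full generator: genotypes -> phenotypes -> serum -> missingness.

    Deterministic given (config, seed): stage streams are spawned from
    ``SeedSequence(seed)`` in a fixed order.
    """
    if config is None:
        config = GeneratorConfig()
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_pc, rng_geno, rng_pheno, rng_serum, rng_miss = (
        np.random.default_rng(s) for s in streams
    )
    definitions = load_score_definitions()

    pcs = pd.DataFrame(
        rng_pc.normal(size=(config.n, config.n_pcs)),
        columns=[f"pc{i}" for i in range(1, config.n_pcs + 1)],
    )
    dosages = simulate_genotypes(
        config, rng_geno, definitions, pc1=pcs["pc1"].to_numpy()
    )
    pcs.index = dosages.individuals
    truth = _true_scores(dosages, definitions)
    cohort = simulate_phenotypes(dosages, config, rng_pheno, definitions, pcs=pcs)
    cohort, noise_params = simulate_serum(cohort, truth, config, rng_serum)
    cohort = _apply_missingness(cohort, config, rng_miss)

    sigma = expected_score_covariance(definitions, config.allele_freqs)
    direct = {
        "vitd": solve_direct_effects(sigma, config.effects.vitd_marginal).to_dict(),
        "reflectance": solve_direct_effects(
            sigma, config.effects.reflectance_marginal
        ).to_dict(),
    }
    return SimulatedCohort(
        dosages=dosages,
        cohort=cohort,
        true_scores=truth,
        direct_effects=direct,
        config=config,
        seed=seed,
        noise_params=noise_params,
    )
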