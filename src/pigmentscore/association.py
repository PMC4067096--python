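"""Derived-variable coding and the adjusted association suite.

This module holds the statistical battery applied to the cohort: recoding
of repeated freckle/sunburn observations into single binary exposures, mole
quartiles, age/sex/PC-adjusted linear and logistic regressions, one-way
ANOVA and Welch t-tests for group comparisons, likelihood-ratio tests for
score-by-sex interaction, and squared semipartial correlations for the
unique variance contribution of each genetic score.

Missing data are handled by complete-case analysis throughout: every fit
drops rows with any missing value among its own variables, and reports the
n actually used.  Model fitting is delegated to statsmodels (OLS / Logit);
the coding rules, alignment and variance decomposition are defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import (
    DegenerateBinsError,
    InsufficientDataError,
    RankDeficiencyError,
    SchemaError,
    SeparationError,
    ValidationError,
)

DEFAULT_PCS = tuple(f"pc{i}" for i in range(1, 11))


# ---------------------------------------------------------------------------
# Derived-variable coding
# ---------------------------------------------------------------------------

def _check_binary(x, label):
    vals = pd.Series(x).dropna().unique()
    bad = [v for v in vals if v not in (0, 1, 0.0, 1.0)]
    if bad:
        raise ValidationError(f"{label}: non-binary codes {bad}")


def combine_freckles(f49, f61):
    """Combine the 49- and 61-month freckle observations into one binary.

    1 = at least one freckle at either age; 0 = none at both.  A missing
    49-month value with a valid 61-month response is coded from the latter;
    "no freckles" at 49 months with the 61-month response missing stays
    missing (the child may have developed freckles unobserved).
    """
    f49 = pd.Series(f49, dtype=float) if not isinstance(f49, pd.Series) else f49.astype(float)
    f61 = pd.Series(f61, dtype=float) if not isinstance(f61, pd.Series) else f61.astype(float)
    _check_binary(f49, "freckles at 49 months")
    _check_binary(f61, "freckles at 61 months")
    out = pd.Series(np.nan, index=f49.index, dtype=float)
    out[(f49 == 1) | (f61 == 1)] = 1.0
    out[(f49 == 0) & (f61 == 0)] = 0.0
    out[f49.isna() & f61.notna()] = f61[f49.isna() & f61.notna()]
    # f49 == 0 & f61 missing stays NaN by construction
    return out


def combine_sunburn(responses: pd.DataFrame):
    """Any occurrence of bad sunburn over the six questionnaire sweeps.

    1 if any sweep reports a bad burn; 0 only if all six report none; a
    child with no reported burn but any missing sweep is coded missing.
    """
    if responses.shape[1] != 6:
        raise ValidationError(
            f"expected the six questionnaire responses, got {responses.shape[1]} columns"
        )
    responses = responses.astype(float)
    for c in responses.columns:
        _check_binary(responses[c], str(c))
    any_burn = (responses == 1).any(axis=1)
    all_clear = (responses == 0).all(axis=1)
    out = pd.Series(np.nan, index=responses.index, dtype=float)
    out[any_burn] = 1.0
    out[~any_burn & all_clear] = 0.0
    return out


def quartile_bins(values) -> tuple[pd.Series, list[str]]:
    """Quartile labels Q1-Q4 for a count variable, ties to the lower bin.

    Cut points are the sample 25/50/75 percentiles; a value equal to a cut
    point is assigned to the lower quartile.  Returns the per-individual
    labels (NaN preserved) and bin-range strings formatted ``Q1 (0-6)``.
    """
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    observed = s.dropna()
    if len(observed) < 4:
        raise InsufficientDataError(f"need at least 4 non-missing values, got {len(observed)}")
    if observed.nunique() == 1:
        raise DegenerateBinsError("all values identical; quartiles are undefined")
    cuts = np.percentile(observed, [25, 50, 75])
    labels = pd.Series(np.nan, index=s.index, dtype=object)
    edges = [-np.inf, *cuts, np.inf]
    names = ["Q1", "Q2", "Q3", "Q4"]
    ranges = []
    for i, name in enumerate(names):
        in_bin = (s > edges[i]) & (s <= edges[i + 1])  # right-closed: ties go low
        labels[in_bin] = name
        members = observed[(observed > edges[i]) & (observed <= edges[i + 1])]
        if len(members):
            ranges.append(f"{name} ({members.min():g}-{members.max():g})")
        else:
            ranges.append(f"{name} (empty)")
    return labels, ranges


def total_mole_count(arm_counts, leg_counts):
    """Total mole count: sum of counts on arms and legs."""
    arms = np.asarray(arm_counts, dtype=float)
    legs = np.asarray(leg_counts, dtype=float)
    if np.nanmin(arms, initial=0) < 0 or np.nanmin(legs, initial=0) < 0:
        raise ValidationError("mole counts must be non-negative")
    total = arms + legs
    return float(total) if total.ndim == 0 else total


# ---------------------------------------------------------------------------
# Regression machinery
# ---------------------------------------------------------------------------

@dataclass
class AssocResult:
    """One exposure-outcome fit: effect, Wald 95% CI, p, n, R-squareds.

    ``effect`` is a per-unit mean difference for linear outcomes and a
    log-odds per unit for logistic ones (``odds_ratio`` = exp(effect)).
    """

    exposure: str
    outcome: str
    effect: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    model_r2: float = np.nan
    semipartial_r2: float = np.nan
    odds_ratio: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


def _design(data: pd.DataFrame, outcome: str, exposure: str, covariates: Sequence[str]):
    needed = [outcome, exposure, *covariates]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise SchemaError(missing)
    frame = data[needed].dropna(axis=0, how="any")
    y = frame[outcome].astype(float)
    x = sm.add_constant(frame[[exposure, *covariates]].astype(float), has_constant="add")
    return y, x, frame


def _check_rank(x: pd.DataFrame):
    arr = x.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        offenders = []
        for j in range(1, arr.shape[1]):
            sub = arr[:, : j + 1]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                offenders.append(str(x.columns[j]))
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {arr.shape[1]}); "
            f"collinear columns: {', '.join(offenders) or 'unknown'}",
            columns=offenders,
        )


def fit_linear_adjusted(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    with_semipartial: bool = False,
) -> AssocResult:
    """OLS of ``outcome`` on ``exposure`` plus covariates (complete cases).

    The reported effect is the exposure coefficient with its Wald 95% CI and
    p-value; ``model_r2`` is the full-model R-squared and, when requested,
    ``semipartial_r2`` the increment in R-squared over the covariate-only
    model — the exposure's unique variance share.
    """
    y, x, frame = _design(data, outcome, exposure, covariates)
    if len(frame) < x.shape[1] + 1:  # at least one residual degree of freedom
        raise InsufficientDataError(
            f"{len(frame)} complete cases for {x.shape[1]} parameters"
        )
    _check_rank(x)
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int().loc[exposure]
    sp = np.nan
    if with_semipartial:
        sp = _semipartial_from_frame(frame, outcome, exposure, list(covariates))
    return AssocResult(
        exposure=exposure,
        outcome=outcome,
        effect=float(fit.params[exposure]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues[exposure]),
        n=int(fit.nobs),
        model_r2=float(fit.rsquared),
        semipartial_r2=sp,
    )


def fit_logistic_adjusted(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
) -> AssocResult:
    """Maximum-likelihood logistic fit; effect on the log-odds scale."""
    y, x, frame = _design(data, outcome, exposure, covariates)
    classes = set(y.unique())
    if not classes <= {0.0, 1.0}:
        raise ValidationError(f"outcome {outcome!r} is not binary: {sorted(classes)}")
    if len(classes) < 2:
        raise ValidationError(f"outcome {outcome!r} has a single class; cannot fit")
    _check_rank(x)
    try:
        fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed ({exc}); check for separation") from exc
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError(
            "logistic fit did not converge; outcome may be perfectly separated by "
            f"{exposure!r} or a covariate"
        )
    ci = fit.conf_int().loc[exposure]
    return AssocResult(
        exposure=exposure,
        outcome=outcome,
        effect=float(fit.params[exposure]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues[exposure]),
        n=int(fit.nobs),
        model_r2=float(fit.prsquared),
        odds_ratio=float(np.exp(fit.params[exposure])),
    )


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    groups: pd.DataFrame  # mean, sd, n per group


def anova_oneway(values, groups) -> AnovaResult:
    """Classical one-way ANOVA with a per-group mean +/- SD table."""
    frame = pd.DataFrame({"value": values, "group": groups}).dropna()
    summary = frame.groupby("group", sort=False, observed=True)["value"].agg(["mean", "std", "count"])
    if len(summary) < 2:
        raise ValidationError("need at least two groups")
    if (summary["count"] < 2).any():
        small = summary.index[summary["count"] < 2].tolist()
        raise ValidationError(f"singleton group(s): {small}")
    samples = [g["value"].to_numpy() for _, g in frame.groupby("group", sort=False, observed=True)]
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return AnovaResult(0.0, 1.0, summary.rename(columns={"count": "n", "std": "sd"}))
    f, p = stats.f_oneway(*samples)
    return AnovaResult(float(f), float(p), summary.rename(columns={"count": "n", "std": "sd"}))


@dataclass
class TTestResult:
    difference: float  # mean(b) - mean(a)
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int


def t_test_means(a, b, welch: bool = True) -> TTestResult:
    """Two-sample t-test of mean(b) - mean(a); Welch form by default."""
    a = np.asarray(pd.Series(a).dropna(), dtype=float)
    b = np.asarray(pd.Series(b).dropna(), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs at least two observations")
    diff = b.mean() - a.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if diff == 0:
            return TTestResult(0.0, 0.0, 0.0, 1.0, len(a), len(b))
        return TTestResult(float(diff), float(diff), float(diff), 0.0, len(a), len(b))
    if welch:
        se = np.sqrt(va / len(a) + vb / len(b))
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        _, p = stats.ttest_ind(b, a, equal_var=False)
    else:
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
        se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        df = len(a) + len(b) - 2
        _, p = stats.ttest_ind(b, a, equal_var=True)
    tcrit = stats.t.ppf(0.975, df)
    return TTestResult(
        float(diff), float(diff - tcrit * se), float(diff + tcrit * se),
        float(p), len(a), len(b),
    )


@dataclass
class LrtResult:
    lrt_statistic: float
    df: int
    p_value: float
    n: int


def lrt_interaction(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    modifier: str,
    covariates: Sequence[str] = (),
    logistic: bool = False,
) -> LrtResult:
    """Likelihood-ratio test for an exposure-by-modifier interaction.

    Both models (with and without the product term) are fitted on the same
    complete-case rows; the statistic is 2*(llf_full - llf_reduced) with one
    degree of freedom, referred to the chi-square distribution.
    """
    y, x_red, frame = _design(data, outcome, exposure, [modifier, *covariates])
    x_full = x_red.copy()
    x_full[f"{exposure}:{modifier}"] = x_full[exposure] * x_full[modifier]
    interaction = x_full[f"{exposure}:{modifier}"]
    if np.allclose(interaction, 0):
        # degenerate modifier: full and reduced fits coincide
        return LrtResult(0.0, 1, 1.0, len(frame))
    _check_rank(x_red)
    if np.linalg.matrix_rank(x_full.to_numpy(float)) < x_full.shape[1]:
        # product column collinear with main effects: no extra information
        return LrtResult(0.0, 1, 1.0, len(frame))
    model = sm.Logit if logistic else sm.OLS
    kwargs = {"disp": 0} if logistic else {}
    llf_red = model(y, x_red).fit(**kwargs).llf
    llf_full = model(y, x_full).fit(**kwargs).llf
    statistic = max(0.0, 2.0 * (llf_full - llf_red))
    return LrtResult(float(statistic), 1, float(stats.chi2.sf(statistic, 1)), len(frame))


def _r2(frame: pd.DataFrame, outcome: str, predictors: list[str], check_rank=False) -> float:
    y = frame[outcome].to_numpy(float)
    x = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(float) for c in predictors])
    if check_rank and np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficiencyError(f"model with {predictors} is rank deficient")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - float((resid**2).sum() / sst) if sst > 0 else 0.0


def _semipartial_from_frame(frame, outcome, exposure, covariates):
    # a collinear exposure adds nothing (least-squares projection unchanged);
    # only a rank-deficient *reduced* model is an error
    full = _r2(frame, outcome, [exposure, *covariates])
    reduced = _r2(frame, outcome, covariates, check_rank=True) if covariates else 0.0
    return max(0.0, full - reduced)


def semipartial_r2(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
) -> float:
    """Squared semipartial correlation of ``exposure`` with ``outcome``.

    The increment in model R-squared when the exposure joins the covariates,
    i.e. the share of outcome variance uniquely attributable to the exposure.
    Both fits use the identical complete-case rows.
    """
    needed = [outcome, exposure, *covariates]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise SchemaError(missing)
    frame = data[needed].dropna(axis=0, how="any")
    if len(frame) < len(needed) + 2:
        raise InsufficientDataError(f"{len(frame)} complete cases")
    return _semipartial_from_frame(frame, outcome, exposure, list(covariates))


# ---------------------------------------------------------------------------
# The published analysis suite
# ---------------------------------------------------------------------------

SUITE_REQUIRED = ("sex", "age_at_draw_months", "deseasonalized_25ohd") + DEFAULT_PCS


def run_paper_suite(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    pcs: Sequence[str] = DEFAULT_PCS,
) -> dict[str, pd.DataFrame]:
    """Run the full association battery and return report tables.

    Emits (as a dict of DataFrames):

    - ``reflectance``: each score vs skin reflectance, unadjusted and
      adjusted for age at the skin exam, sex and the PCs, with the
      semipartial R-squared (as a fraction and in %) and the unadjusted F.
    - ``categories``: per-category score means +/- SD, N, 25(OH)D means
      +/- SD and ANOVA p-values (raw and PC-adjusted score means are both
      tested) for the tanning, sunburn, freckle and mole-quartile groupings
      present in the cohort.
    - ``vitamin_d``: each score vs deseasonalized 25(OH)D adjusted for age
      at blood draw, sex and PCs, with semipartial R-squared.
    - ``vitamin_d_mutual``: the same models with the other two scores as
      additional covariates.
    - ``sex_stratified``: the adjusted reflectance models per sex.
    - ``interactions``: likelihood-ratio p-values for score-by-sex
      interaction on reflectance (linear) and any-freckles (logistic).
    """
    pcs = list(pcs)
    missing = [c for c in (*SUITE_REQUIRED[:3], *pcs) if c not in cohort.columns]
    if missing:
        raise SchemaError(missing)
    data = cohort.join(scores, how="left")
    score_names = list(scores.columns)

    tables: dict[str, pd.DataFrame] = {}

    # --- reflectance (Table-2 style) ---
    if "reflectance" in data.columns:
        rows = []
        age_col = "age_reflectance_months" if "age_reflectance_months" in data else None
        adjust = ([age_col] if age_col else []) + ["sex", *pcs]
        for s in score_names:
            una = fit_linear_adjusted(data, "reflectance", s, with_semipartial=True)
            adj = fit_linear_adjusted(data, "reflectance", s, adjust, with_semipartial=True)
            f_stat = una.n - 2 > 0 and _f_from_r2(una.model_r2, una.n)
            rows.append(
                {
                    "score": s,
                    "effect_unadjusted": una.effect,
                    "ci_low_unadjusted": una.ci_low,
                    "ci_high_unadjusted": una.ci_high,
                    "p_unadjusted": una.p_value,
                    "r2": una.model_r2,
                    "r2_percent": 100 * una.model_r2,
                    "f_statistic": f_stat,
                    "effect_adjusted": adj.effect,
                    "ci_low_adjusted": adj.ci_low,
                    "ci_high_adjusted": adj.ci_high,
                    "p_adjusted": adj.p_value,
                    "semipartial_r2": adj.semipartial_r2,
                    "semipartial_r2_percent": 100 * adj.semipartial_r2,
                    "n": adj.n,
                }
            )
        tables["reflectance"] = pd.DataFrame(rows).set_index("score")

        # sex-stratified adjusted models
        strat = []
        for sex_code, label in ((0, "boys"), (1, "girls")):
            subset = data[data["sex"] == sex_code]
            for s in score_names:
                adj = fit_linear_adjusted(
                    subset, "reflectance", s,
                    ([age_col] if age_col else []) + pcs,
                    with_semipartial=True,
                )
                strat.append(
                    {
                        "sex": label,
                        "score": s,
                        "effect": adj.effect,
                        "ci_low": adj.ci_low,
                        "ci_high": adj.ci_high,
                        "p": adj.p_value,
                        "semipartial_r2": adj.semipartial_r2,
                        "n": adj.n,
                    }
                )
        tables["sex_stratified"] = pd.DataFrame(strat).set_index(["sex", "score"])

    # --- categorical groupings (Table-3 style) ---
    cat_specs = [
        ("tanning_category", "skin colour change"),
        ("badly_burnt", "child badly burnt"),
        ("any_freckles", "any freckles"),
        ("mole_quartile_49m", "mole count 49 months"),
        ("mole_quartile_61m", "mole count 61 months"),
        ("mole_quartile_186m", "mole count 186 months"),
    ]
    cat_rows = []
    pc_resid = _pc_residualized(data, score_names, pcs)
    for column, label in cat_specs:
        if column not in data.columns:
            continue
        groups = data[column]
        for s in score_names:
            res = anova_oneway(data[s], groups)
            res_adj = anova_oneway(pc_resid[s], groups)
            for g, row in res.groups.iterrows():
                cat_rows.append(
                    {
                        "grouping": label,
                        "category": g,
                        "score": s,
                        "mean": row["mean"],
                        "sd": row["sd"],
                        "n": int(row["n"]),
                        "anova_p": res.p_value,
                        "anova_p_pc_adjusted": res_adj.p_value,
                    }
                )
        if "deseasonalized_25ohd" in data:
            res_d = anova_oneway(data["deseasonalized_25ohd"], groups)
            for g, row in res_d.groups.iterrows():
                cat_rows.append(
                    {
                        "grouping": label,
                        "category": g,
                        "score": "deseasonalized_25ohd",
                        "mean": row["mean"],
                        "sd": row["sd"],
                        "n": int(row["n"]),
                        "anova_p": res_d.p_value,
                        "anova_p_pc_adjusted": np.nan,
                    }
                )
    if cat_rows:
        tables["categories"] = pd.DataFrame(cat_rows).set_index(
            ["grouping", "category", "score"]
        )

    # --- 25(OH)D (Table-4 style) ---
    adjust_vd = ["age_at_draw_months", "sex", *pcs]
    rows, mutual = [], []
    for s in score_names:
        adj = fit_linear_adjusted(
            data, "deseasonalized_25ohd", s, adjust_vd, with_semipartial=True
        )
        rows.append(
            {
                "score": s,
                "effect": adj.effect,
                "ci_low": adj.ci_low,
                "ci_high": adj.ci_high,
                "p": adj.p_value,
                "semipartial_r2": adj.semipartial_r2,
                "n": adj.n,
            }
        )
        others = [o for o in score_names if o != s]
        mut = fit_linear_adjusted(
            data, "deseasonalized_25ohd", s, adjust_vd + others, with_semipartial=True
        )
        mutual.append(
            {
                "score": s,
                "effect": mut.effect,
                "ci_low": mut.ci_low,
                "ci_high": mut.ci_high,
                "p": mut.p_value,
                "semipartial_r2": mut.semipartial_r2,
                "n": mut.n,
            }
        )
    tables["vitamin_d"] = pd.DataFrame(rows).set_index("score")
    tables["vitamin_d_mutual"] = pd.DataFrame(mutual).set_index("score")

    # --- score-by-sex interactions ---
    inter_rows = []
    if "reflectance" in data.columns:
        age_cov = ["age_reflectance_months"] if "age_reflectance_months" in data else []
        for s in score_names:
            res = lrt_interaction(data, "reflectance", s, "sex", age_cov + pcs)
            inter_rows.append(
                {"outcome": "reflectance", "score": s, "lrt": res.lrt_statistic,
                 "df": res.df, "p": res.p_value, "n": res.n}
            )
    if "any_freckles" in data.columns:
        for s in score_names:
            try:
                res = lrt_interaction(
                    data, "any_freckles", s, "sex", pcs, logistic=True
                )
            except (SeparationError, InsufficientDataError):
                continue
            inter_rows.append(
                {"outcome": "any_freckles", "score": s, "lrt": res.lrt_statistic,
                 "df": res.df, "p": res.p_value, "n": res.n}
            )
    if inter_rows:
        tables["interactions"] = pd.DataFrame(inter_rows).set_index(["outcome", "score"])

    return tables


def _f_from_r2(r2: float, n: int) -> float:
    """F statistic of the simple (one-predictor) regression from its R^2."""
    if r2 >= 1.0:
        return np.inf
    return float(r2 / (1 - r2) * (n - 2))


def _pc_residualized(data: pd.DataFrame, score_names, pcs) -> pd.DataFrame:
    """Scores residualized on the PCs (mesor-free; used for adjusted ANOVA)."""
    out = {}
    x_cols = [c for c in pcs if c in data.columns]
    for s in score_names:
        frame = data[[s, *x_cols]].dropna()
        x = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(float) for c in x_cols])
        y = frame[s].to_numpy(float)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = pd.Series(y - x @ beta + y.mean(), index=frame.index)
        out[s] = resid.reindex(data.index)
    return pd.DataFrame(out, index=data.index)
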