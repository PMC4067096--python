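"""Cosinor modelling of the annual cycle in serum 25(OH)D.

Serum 25-hydroxyvitamin D tracks recent UVR-B exposure, so concentrations
follow a strong annual sinusoid against date of blood collection.  The
habitual (season-free) level of each individual is obtained by fitting

    total ~ mesor + beta_cos * cos(2*pi*t/T) + beta_sin * sin(2*pi*t/T)

by ordinary least squares, with t measured in days since a fixed epoch
(January 1 of the earliest draw year) and T = 365.25 days by default, and
taking the residuals.  By default residuals are recentred by adding back
the mesor so downstream effect estimates stay on the nmol/l scale.

Extra harmonics (2*pi*k*t/T for k = 2, ...) can be added through the
``harmonics`` argument; the single-harmonic model is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, RankDeficiencyError, ValidationError

DEFAULT_PERIOD = 365.25

#: Assessment-priority rule for children with serum from several clinic
#: visits: prefer the age-9 sample, then age 11, then age 7.
ASSESSMENT_PRIORITY = (9, 11, 7)


def total_25ohd(d3, d2):
    """Total 25(OH)D as the sum of the D3 and D2 metabolites (nmol/l)."""
    d3 = np.asarray(d3, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(d3 < 0) or np.any(d2 < 0):
        raise ValidationError("25(OH)D concentrations must be non-negative")
    total = d3 + d2
    return float(total) if total.ndim == 0 else total


@dataclass(frozen=True)
class SeasonalModel:
    """Fitted cosinor parameters.

    ``harmonic_coefs`` holds (cos, sin) pairs for harmonics beyond the first;
    amplitude and acrophase are derived from the annual harmonic only.
    """

    mesor: float
    beta_cos: float
    beta_sin: float
    period: float = DEFAULT_PERIOD
    epoch: pd.Timestamp = pd.Timestamp("2000-01-01")
    r_squared: float = np.nan
    harmonic_coefs: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    @property
    def amplitude(self) -> float:
        """Half the peak-to-trough swing of the annual harmonic (nmol/l)."""
        return float(np.hypot(self.beta_cos, self.beta_sin))

    @property
    def acrophase(self) -> float:
        """Peak timing as days after January 1, in [0, period)."""
        phase = np.arctan2(self.beta_sin, self.beta_cos)  # radians of peak
        days = (phase / (2 * np.pi)) * self.period
        return float(np.mod(days, self.period))

    def design(self, t: np.ndarray) -> np.ndarray:
        omega = 2 * np.pi / self.period
        cols = [np.ones_like(t), np.cos(omega * t), np.sin(omega * t)]
        for k in range(2, 2 + len(self.harmonic_coefs)):
            cols.extend([np.cos(k * omega * t), np.sin(k * omega * t)])
        return np.column_stack(cols)

    def predict(self, dates) -> np.ndarray:
        """Fitted seasonal curve at the given calendar dates."""
        t = days_since_epoch(dates, self.epoch)
        coefs = [self.mesor, self.beta_cos, self.beta_sin]
        for c, s in self.harmonic_coefs:
            coefs.extend([c, s])
        return self.design(t) @ np.asarray(coefs)


def days_since_epoch(dates, epoch: pd.Timestamp) -> np.ndarray:
    dates = pd.to_datetime(pd.Index(np.atleast_1d(dates)))
    return ((dates - epoch) / pd.Timedelta(days=1)).to_numpy(dtype=float)


def fit_cosinor(
    dates,
    values,
    period: float = DEFAULT_PERIOD,
    harmonics: int = 1,
    epoch: pd.Timestamp | None = None,
) -> SeasonalModel:
    """Least-squares cosinor fit of a serum series against draw dates.

    Parameters
    ----------
    dates : datetime-like sequence
        Blood-draw dates.
    values : float sequence
        Total 25(OH)D (nmol/l), aligned with ``dates``.
    period : float
        Cycle length in days; 365.25 for the annual rhythm.
    harmonics : int
        Number of harmonics; 1 fits the plain annual sinusoid.
    epoch : Timestamp, optional
        Time origin; defaults to January 1 of the earliest draw year.  The
        choice only rotates the (beta_cos, beta_sin) pair — amplitude, mesor
        and residuals are epoch-invariant.
    """
    if period <= 0:
        raise ValidationError(f"period must be positive, got {period}")
    if harmonics < 1:
        raise ValidationError("need at least one harmonic")
    dates = pd.to_datetime(pd.Index(dates))
    y = np.asarray(values, dtype=float)
    if len(dates) != len(y):
        raise ValidationError("dates and values must be aligned")
    ok = ~(pd.isna(dates) | np.isnan(y))
    dates, y = dates[ok], y[ok]
    if len(y) < 2 + 2 * harmonics:
        raise InsufficientDataError(
            f"need at least {2 + 2 * harmonics} measures for {harmonics} harmonic(s)"
        )
    if dates.nunique() < 2:
        raise RankDeficiencyError(
            "all draw dates identical; the seasonal curve is unidentifiable",
            columns=["cos", "sin"],
        )
    if epoch is None:
        epoch = pd.Timestamp(year=dates.min().year, month=1, day=1)

    t = days_since_epoch(dates, epoch)
    omega = 2 * np.pi / period
    cols = [np.ones_like(t)]
    for k in range(1, harmonics + 1):
        cols.extend([np.cos(k * omega * t), np.sin(k * omega * t)])
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficiencyError(
            "cosinor design is rank deficient (dates do not span the cycle)"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - fitted) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    extra = tuple((float(beta[1 + 2 * k]), float(beta[2 + 2 * k])) for k in range(1, harmonics))
    return SeasonalModel(
        mesor=float(beta[0]),
        beta_cos=float(beta[1]),
        beta_sin=float(beta[2]),
        period=period,
        epoch=epoch,
        r_squared=r2,
        harmonic_coefs=extra,
    )


def residualize(dates, values, model: SeasonalModel, recenter: bool = True):
    """Deseasonalized 25(OH)D: observed minus the fitted seasonal curve.

    With ``recenter=True`` (default) the mesor is added back, so the output
    is on the nmol/l scale and its mean over the fitting sample equals the
    mesor; with ``recenter=False`` raw residuals (mean ~ 0) are returned.
    """
    y = np.asarray(values, dtype=float)
    resid = y - model.predict(dates)
    if recenter:
        resid = resid + model.mesor
    if isinstance(values, pd.Series):
        return pd.Series(resid, index=values.index, name="deseasonalized_25ohd")
    return resid


def deseasonalize(
    frame: pd.DataFrame,
    date_column: str = "draw_date",
    total_column: str = "total_25ohd",
    period: float = DEFAULT_PERIOD,
    harmonics: int = 1,
    recenter: bool = True,
) -> tuple[pd.Series, SeasonalModel]:
    """Fit the cosinor on a phenotype table and return habitual 25(OH)D.

    Rows with a missing date or total are excluded from the fit and receive
    NaN in the output, which is aligned to ``frame.index``.
    """
    dates = pd.to_datetime(frame[date_column])
    y = frame[total_column].astype(float)
    ok = dates.notna() & y.notna()
    model = fit_cosinor(dates[ok], y[ok], period=period, harmonics=harmonics)
    out = pd.Series(np.nan, index=frame.index, name="deseasonalized_25ohd")
    out[ok] = residualize(dates[ok], y[ok], model, recenter=recenter)
    return out, model


def select_serum_assessment(
    long_frame: pd.DataFrame,
    individual_column: str = "individual",
    assessment_column: str = "assessment_age_years",
    priority: tuple[int, ...] = ASSESSMENT_PRIORITY,
) -> pd.DataFrame:
    """Pick one serum measure per child by assessment priority.

    Children sampled at several clinic visits contribute the highest-priority
    assessment only (default: age 9, else 11, else 7).  Rows whose assessment
    is not in ``priority`` are dropped.
    """
    rank = {age: i for i, age in enumerate(priority)}
    frame = long_frame[long_frame[assessment_column].isin(rank)].copy()
    frame["_rank"] = frame[assessment_column].map(rank)
    frame = frame.sort_values("_rank", kind="stable")
    out = frame.drop_duplicates(subset=individual_column, keep="first")
    return out.drop(columns="_rank").sort_index()
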