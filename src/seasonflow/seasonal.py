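"""Harmonic (cosinor) seasonality inference.

Each species' weekly series (typically the STL seasonal component of the
rclr-transformed abundances) is fitted by ordinary least squares to a
single fixed-period harmonic

    y(t) = m + A * cos(2*pi*t/P - phi),      P = 52 weeks,

via the linear basis {1, cos(2*pi*t/P), sin(2*pi*t/P)}.  Significance of
the seasonal response is the F-test of the two trigonometric terms
jointly against the intercept-only model, with a 1% threshold.  The peak
week is where the fitted cosine attains its maximum; a residual
bootstrap provides a circular 95% confidence interval.  Seasonal
strength Fs compares the variance of the STL remainder with the variance
of the seasonal component, and the fitted peak's calendar position
assigns each significant species to an astronomical-season cohort
(winter, spring, summer, autumn).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from seasonflow.decomposition import Decomposition, WeeklySeries

__all__ = [
    "COHORTS",
    "STRENGTH_CUTPOINTS",
    "HarmonicFit",
    "SeasonalResult",
    "season_of_day",
    "fit_harmonic",
    "peak_confidence_interval",
    "seasonal_strength",
    "strength_category",
    "assign_cohort",
]

COHORTS = ("winter", "spring", "summer", "autumn")

# Astronomical-season windows on a 365-day calendar (day-of-year,
# inclusive).  Winter wraps the year boundary: 21 Dec (355) - 20 Mar (79).
# Spring: 21 Mar (80) - 21 Jun (172).  Summer: 22 Jun (173) - 22 Sep (265).
# Autumn: 23 Sep (266) - 20 Dec (354); the two-day overlap the verbal
# definitions leave at 21-22 Dec is resolved in favour of winter, which
# begins astronomically on 21 Dec.
_WINTER_START = 355
_SPRING_START = 80
_SUMMER_START = 173
_AUTUMN_START = 266

# Fs cut points for (very strong, strong, moderate, weak) lower bounds;
# anything below the last is "very weak".  Boundaries are left-closed.
STRENGTH_CUTPOINTS = (0.75, 0.55, 0.35, 0.15)


def season_of_day(day_of_year: float) -> str:
    """Map a day-of-year (1..365, fractional allowed) to its season.

    This is the single source of truth for cohort windows: the synthetic
    generator's ground-truth labels and :func:`assign_cohort` both call it.
    """
    d = float(day_of_year)
    if not (1 <= d <= 366):
        raise ValueError(f"day_of_year must be in [1, 366], got {d}")
    if d >= _WINTER_START or d < _SPRING_START:
        return "winter"
    if d < _SUMMER_START:
        return "spring"
    if d < _AUTUMN_START:
        return "summer"
    return "autumn"


@dataclass(frozen=True)
class HarmonicFit:
    """A fitted annual harmonic on a weekly grid.

    ``peak_t`` is the peak position on the fit's own weekly time axis
    (in (0, 52], where t = 1 is the first grid week); ``peak_doy`` and
    ``peak_week`` are the corresponding calendar day-of-year and
    real-valued calendar week (day_of_year * 52/365).
    """

    m: float
    amplitude: float
    phase: float
    p_value: float
    peak_t: float
    peak_doy: float
    peak_week: float
    n_weeks: int
    start_doy: float
    residuals: np.ndarray
    fitted: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "residuals", np.asarray(self.residuals, float))
        object.__setattr__(self, "fitted", np.asarray(self.fitted, float))


@dataclass(frozen=True)
class SeasonalResult:
    """Per-species seasonality summary."""

    species_id: str
    fit: HarmonicFit
    fs: float
    strength: str
    cohort: str
    ci_low: float | None = None
    ci_high: float | None = None


def _design(n: int, period: float = 52.0) -> np.ndarray:
    t = np.arange(1, n + 1, dtype=float)
    w = 2.0 * np.pi * t / period
    return np.column_stack([np.ones(n), np.cos(w), np.sin(w)])


def _peak_from_coefs(beta_c: float, beta_s: float, period: float = 52.0) -> float:
    """Peak position t in (0, period] of A*cos(2*pi*t/period - phi)."""
    phi = np.arctan2(beta_s, beta_c)
    t_peak = (phi * period / (2.0 * np.pi)) % period
    if t_peak == 0.0:
        t_peak = period
    return float(t_peak)


def _week_of_doy(doy: float | np.ndarray) -> float | np.ndarray:
    """Continuous calendar week position of a day-of-year (1..365).

    Day 1 maps to week 1.0, day 8 to week 2.0, ...; the year's 365th day
    folds from week 53.0 back to 1.0 (the calendar circle has 52 weeks
    plus one day, a <1-day distortion absorbed by the weekly grid).
    """
    week = (np.asarray(doy, float) - 1.0) / 7.0 + 1.0
    week = np.where(week >= 53.0, week - 52.0, week)
    return float(week) if np.ndim(doy) == 0 else week


def _calendar_peak(t_peak: float, start_doy: float) -> tuple[float, float]:
    """Convert a peak on the series' weekly axis to calendar position.

    Week t = 1 is the week beginning on the series' start date, so a peak
    at t corresponds to ``(t - 1) * 7`` days after the start.
    """
    doy = (start_doy - 1.0 + (t_peak - 1.0) * 7.0) % 365.0 + 1.0
    return float(doy), float(_week_of_doy(doy))


def fit_harmonic(s: WeeklySeries, period: float = 52.0) -> HarmonicFit:
    """Fit ``y = m + A*cos(2*pi*t/period - phi)`` by OLS on a weekly grid.

    The p-value is the F-test of the cosine and sine terms jointly
    against the intercept-only model (2 numerator df).  A constant series
    yields ``amplitude = 0`` and ``p_value = 1``.
    """
    y = np.asarray(s.values, dtype=float)
    n = y.size
    if n < period + 3:
        raise ValueError(
            f"series too short for harmonic fit: {n} < {period + 3:.0f} weeks"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    X = _design(n, period)
    res = sm.OLS(y, X).fit()
    beta = res.params
    fitted = np.asarray(res.fittedvalues)
    resid = np.asarray(res.resid)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    scale = max(1.0, float(np.abs(y).max()))
    if np.ptp(y) <= 1e-12 * scale:
        # constant series: no seasonal signal by definition
        p_value = 1.0
    elif sse <= np.finfo(float).eps * sst:
        # numerically exact fit
        p_value = 0.0
    else:
        # regression F-test: both trigonometric terms jointly vs intercept
        p_value = float(res.f_pvalue)
    m, beta_c, beta_s = map(float, beta)
    amplitude = float(np.hypot(beta_c, beta_s))
    phase = float(np.arctan2(beta_s, beta_c) % (2.0 * np.pi))
    t_peak = _peak_from_coefs(beta_c, beta_s, period)
    start_doy = float(s.start_date.dayofyear) if s.start_date is not None else 1.0
    peak_doy, peak_week = _calendar_peak(t_peak, start_doy)
    return HarmonicFit(
        m=m,
        amplitude=amplitude,
        phase=phase,
        p_value=p_value,
        peak_t=t_peak,
        peak_doy=peak_doy,
        peak_week=peak_week,
        n_weeks=n,
        start_doy=start_doy,
        residuals=resid,
        fitted=fitted,
    )


def peak_confidence_interval(
    fit: HarmonicFit,
    s: WeeklySeries,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """95% CI for the calendar peak week by residual bootstrap.

    Residuals of the harmonic fit are resampled with replacement, added
    back to the fitted values, and the harmonic is refitted; the peak
    weeks of the refits form the bootstrap distribution.  Percentiles
    are taken on the circle as the shortest arc around the point
    estimate, so intervals wrap correctly across the week-52/week-1
    boundary.  An amplitude at machine zero yields the full-year
    interval.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = fit.n_weeks
    if fit.amplitude < 1e-12:
        return (0.0, 52.0)
    X = _design(n)
    pinv = np.linalg.pinv(X)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_y = fit.fitted[None, :] + fit.residuals[idx]
    betas = boot_y @ pinv.T  # (n_boot, 3)
    t_peaks = (np.arctan2(betas[:, 2], betas[:, 1]) * 52.0 / (2.0 * np.pi)) % 52.0
    doys = (fit.start_doy - 1.0 + (t_peaks - 1.0) * 7.0) % 365.0 + 1.0
    weeks = _week_of_doy(doys)
    # circular deviations from the point estimate, in (-26, 26]
    dev = (weeks - fit.peak_week + 26.0) % 52.0 - 26.0
    alpha = 1.0 - level
    lo, hi = np.percentile(dev, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)])
    ci_low = (fit.peak_week + lo) % 52.0
    ci_high = (fit.peak_week + hi) % 52.0
    if ci_low == 0.0:
        ci_low = 52.0
    if ci_high == 0.0:
        ci_high = 52.0
    return (float(ci_low), float(ci_high))


def seasonal_strength(d: Decomposition) -> float:
    """Seasonal strength Fs = 1 - var(remainder)/(var(remainder)+var(seasonal)).

    Population variances; Fs is clipped to [0, 1].  Fs = 1 means the
    non-trend variation is entirely seasonal; Fs = 0 means none of it is.
    """
    var_r = float(np.var(d.remainder))
    var_s = float(np.var(d.seasonal))
    denom = var_r + var_s
    if denom <= 0.0:
        raise ValueError("degenerate series: seasonal and remainder both constant")
    return float(np.clip(1.0 - var_r / denom, 0.0, 1.0))


def strength_category(fs: float, p_value: float, alpha: float = 0.01) -> str:
    """Map Fs to a verbal strength class, gated on harmonic significance.

    Fs >= 0.75 very strong; [0.55, 0.75) strong; [0.35, 0.55) moderate;
    [0.15, 0.35) weak; < 0.15 very weak.  Non-significant fits
    (p > alpha) are labelled "non-significant" regardless of Fs.
    """
    if not 0.0 <= fs <= 1.0:
        raise ValueError(f"fs must be in [0, 1], got {fs}")
    if p_value > alpha:
        return "non-significant"
    labels = ("very strong", "strong", "moderate", "weak")
    for cut, label in zip(STRENGTH_CUTPOINTS, labels):
        if fs >= cut:
            return label
    return "very weak"


def assign_cohort(fit: HarmonicFit, alpha: float = 0.01) -> str:
    """Assign a seasonal cohort from the fitted peak's calendar position.

    Species with p > alpha fall in the "non-significant" cohort; the
    rest are assigned by the astronomical-season window containing the
    peak day-of-year (see :func:`season_of_day`).
    """
    if fit.p_value > alpha:
        return "non-significant"
    return season_of_day(fit.peak_doy)
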