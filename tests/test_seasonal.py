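"""Harmonic fitting, seasonal strength, peak CIs and cohort assignment."""

import numpy as np
import pytest

from seasonflow.decomposition import Decomposition, WeeklySeries, stl_periodic
from seasonflow.seasonal import (
    HarmonicFit,
    assign_cohort,
    fit_harmonic,
    peak_confidence_interval,
    season_of_day,
    seasonal_strength,
    strength_category,
)
import pandas as pd

JAN1 = pd.Timestamp("2015-01-01")


def cosine_series(peak_t, n=156, m=0.0, amp=1.0, sigma=0.0, seed=0,
                  start=JAN1):
    rng = np.random.default_rng(seed)
    t = np.arange(1, n + 1, dtype=float)
    y = m + amp * np.cos(2 * np.pi * (t - peak_t) / 52)
    if sigma > 0:
        y = y + rng.normal(0, sigma, n)
    return WeeklySeries(y, start_date=start)


def circ_contains(week, lo, hi):
    if lo <= hi:
        return lo <= week <= hi
    return week >= lo or week <= hi


class TestFitHarmonic:
    def test_exact_cosine_recovered(self):
        ws = cosine_series(peak_t=26, m=2.0, amp=3.0)
        fit = fit_harmonic(ws)
        assert fit.m == pytest.approx(2.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-9)
        assert fit.peak_t == pytest.approx(26.0, abs=1e-6)
        # Jan-1 start: grid week 26 is calendar week 26
        assert fit.peak_week == pytest.approx(26.0, abs=1e-6)
        assert fit.p_value < 1e-10

    def test_constant_series_null(self):
        fit = fit_harmonic(WeeklySeries(np.full(156, 3.3), start_date=JAN1))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_harmonic(WeeklySeries(np.zeros(50), start_date=JAN1))

    def test_amplitude_matches_grid_search_oracle(self):
        ws = cosine_series(peak_t=14, amp=1.0, sigma=1.0, seed=11)
        fit = fit_harmonic(ws)
        # independent oracle: grid over phase at 0.01 resolution with
        # closed-form (m, A) per phase, minimising SSE
        t = np.arange(1, 157, dtype=float)
        best_sse, best_a = np.inf, None
        for phi in np.arange(0, 2 * np.pi, 0.01):
            X = np.column_stack([np.ones(156), np.cos(2 * np.pi * t / 52 - phi)])
            beta, res, *_ = np.linalg.lstsq(X, ws.values, rcond=None)
            sse = float(res[0]) if res.size else float(
                np.sum((ws.values - X @ beta) ** 2)
            )
            if sse < best_sse:
                best_sse, best_a = sse, abs(beta[1])
        assert fit.amplitude == pytest.approx(best_a, abs=0.02)

    @pytest.mark.parametrize("shift", [5, 20, 45])
    def test_phase_equivariance_under_circular_shift(self, shift):
        rng = np.random.default_rng(4)
        base = cosine_series(peak_t=10, amp=1.0).values + rng.normal(0, 0.5, 156)
        f0 = fit_harmonic(WeeklySeries(base, start_date=JAN1))
        f1 = fit_harmonic(WeeklySeries(np.roll(base, shift), start_date=JAN1))
        expected = (f0.peak_t + shift - 1) % 52 + 1
        assert f1.peak_t == pytest.approx(expected, abs=1e-6)


class TestPeakConfidenceInterval:
    def test_noise_free_interval_collapses(self):
        ws = cosine_series(peak_t=26, amp=2.0)
        fit = fit_harmonic(ws)
        lo, hi = peak_confidence_interval(fit, ws, n_boot=200, seed=0)
        assert lo == pytest.approx(fit.peak_week, abs=1e-6)
        assert hi == pytest.approx(fit.peak_week, abs=1e-6)

    def test_zero_amplitude_flags_full_year(self):
        ws = WeeklySeries(np.full(156, 1.0), start_date=JAN1)
        fit = fit_harmonic(ws)
        assert peak_confidence_interval(fit, ws, seed=0) == (0.0, 52.0)

    def test_interval_wraps_year_boundary(self):
        ws = cosine_series(peak_t=1, amp=1.0, sigma=1.5, seed=2)
        fit = fit_harmonic(ws)
        lo, hi = peak_confidence_interval(fit, ws, n_boot=1000, seed=7)
        assert circ_contains(fit.peak_week, lo, hi)
        # peak near week 1 with symmetric noise: the interval must span
        # the week-52/week-1 boundary
        assert lo > hi
        assert circ_contains(52.0, lo, hi)
        assert circ_contains(2.0, lo, hi)

    def test_width_and_coverage(self):
        ws = cosine_series(peak_t=30, amp=1.0, sigma=0.3, seed=7)
        fit = fit_harmonic(ws)
        lo, hi = peak_confidence_interval(fit, ws, n_boot=1000, seed=7)
        width = (hi - lo) % 52
        assert width < 6
        true_week = fit_harmonic(cosine_series(peak_t=30, amp=1.0)).peak_week
        covered = 0
        for s in range(200):
            w = cosine_series(peak_t=30, amp=1.0, sigma=0.3, seed=100 + s)
            f = fit_harmonic(w)
            lo, hi = peak_confidence_interval(f, w, n_boot=300, seed=s)
            covered += circ_contains(true_week, lo, hi)
        assert covered / 200 >= 0.90

    def test_deterministic_given_seed(self):
        ws = cosine_series(peak_t=10, amp=1.0, sigma=0.5, seed=3)
        fit = fit_harmonic(ws)
        a = peak_confidence_interval(fit, ws, n_boot=200, seed=5)
        b = peak_confidence_interval(fit, ws, n_boot=200, seed=5)
        assert a == b


def _decomp(seasonal, remainder):
    seasonal = np.asarray(seasonal, float)
    remainder = np.asarray(remainder, float)
    series = WeeklySeries(seasonal + remainder)
    return Decomposition(series=series, trend=np.zeros(seasonal.size),
                         seasonal=seasonal)


class TestSeasonalStrength:
    def test_pure_seasonal_is_one(self):
        alt = np.resize([1.0, -1.0], 104)
        assert seasonal_strength(_decomp(alt, np.zeros(104))) == 1.0

    def test_no_seasonal_is_zero(self):
        alt = np.resize([1.0, -1.0], 104)
        assert seasonal_strength(_decomp(np.zeros(104), alt)) == 0.0

    def test_three_to_one_variance_ratio(self):
        seasonal = np.resize([np.sqrt(3), -np.sqrt(3)], 104)
        remainder = np.resize([1.0, -1.0], 104)
        assert seasonal_strength(_decomp(seasonal, remainder)) == pytest.approx(
            0.75, abs=1e-12
        )

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            seasonal_strength(_decomp(np.zeros(104), np.zeros(104)))

    def test_invariant_to_constant_shift_of_input(self):
        rng = np.random.default_rng(8)
        t = np.arange(1, 157.0)
        y = np.cos(2 * np.pi * t / 52) + rng.normal(0, 0.4, 156)
        f0 = seasonal_strength(stl_periodic(WeeklySeries(y)))
        f1 = seasonal_strength(stl_periodic(WeeklySeries(y + 5.0)))
        assert f0 == pytest.approx(f1, abs=1e-8)


class TestStrengthCategory:
    @pytest.mark.parametrize(
        "fs,p,expected",
        [
            (0.8, 0.001, "very strong"),
            (0.5, 0.001, "moderate"),
            (0.9, 0.02, "non-significant"),
            (0.75, 0.001, "very strong"),   # boundaries left-closed
            (0.55, 0.001, "strong"),
            (0.35, 0.001, "moderate"),
            (0.15, 0.001, "weak"),
            (0.10, 0.001, "very weak"),
            (0.9, 0.01, "very strong"),     # significant at p == alpha
        ],
    )
    def test_categories(self, fs, p, expected):
        assert strength_category(fs, p) == expected

    def test_fs_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            strength_category(1.2, 0.001)


class TestSeasonWindows:
    @pytest.mark.parametrize(
        "doy,season",
        [
            (32, "winter"),    # Feb 1
            (79, "winter"),    # Mar 20
            (80, "spring"),    # Mar 21
            (172, "spring"),   # Jun 21
            (173, "summer"),   # Jun 22
            (265, "summer"),   # Sep 22
            (266, "autumn"),   # Sep 23
            (354, "autumn"),   # Dec 20
            (355, "winter"),   # Dec 21
            (365, "winter"),   # Dec 31
            (1, "winter"),     # Jan 1
        ],
    )
    def test_windows(self, doy, season):
        assert season_of_day(doy) == season

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            season_of_day(0)


class TestAssignCohort:
    @pytest.mark.parametrize(
        "peak_doy,season",
        [(32, "winter"), (120, "spring"), (265, "summer"), (266, "autumn")],
    )
    def test_peak_day_maps_through_windows(self, peak_doy, season):
        # a Jan-1-start series peaking (t-1)*7 days in peaks on doy
        peak_t = (peak_doy - 1) / 7.0 + 1.0
        ws = cosine_series(peak_t=peak_t, amp=2.0)
        fit = fit_harmonic(ws)
        assert fit.peak_doy == pytest.approx(peak_doy, abs=1e-6)
        assert assign_cohort(fit) == season

    def test_non_significant_fit_gets_no_season(self):
        ws = cosine_series(peak_t=10, amp=2.0)
        fit = fit_harmonic(ws)
        ns = HarmonicFit(
            m=fit.m, amplitude=fit.amplitude, phase=fit.phase, p_value=0.02,
            peak_t=fit.peak_t, peak_doy=fit.peak_doy, peak_week=fit.peak_week,
            n_weeks=fit.n_weeks, start_doy=fit.start_doy,
            residuals=fit.residuals, fitted=fit.fitted,
        )
        assert assign_cohort(ns) == "non-significant"

    def test_significant_at_exactly_alpha(self):
        ws = cosine_series(peak_t=10, amp=2.0)
        fit = fit_harmonic(ws)
        at_alpha = HarmonicFit(
            m=fit.m, amplitude=fit.amplitude, phase=fit.phase, p_value=0.01,
            peak_t=fit.peak_t, peak_doy=fit.peak_doy, peak_week=fit.peak_week,
            n_weeks=fit.n_weeks, start_doy=fit.start_doy,
            residuals=fit.residuals, fitted=fit.fitted,
        )
        assert assign_cohort(at_alpha) != "non-significant"
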