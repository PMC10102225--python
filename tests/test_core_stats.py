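"""Unit and property tests for the per-location seasonal-shift statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakeshift.core_stats import (
    MONTH_PER_YEAR_TO_DAYS_PER_DECADE,
    ExclusionCriteria,
    ExclusionReason,
    InsufficientDataError,
    MonthlyTemperatureSeries,
    UndefinedShiftError,
    compute_shift,
    fit_monthly_trend,
    ice_year_fraction,
    seasonal_rate_of_change,
    shift_for_season,
)
from lakeshift.seasons import season_for, moving_windows

from conftest import (
    drift_estimator_value,
    month_phase,
    ols_slope_oracle,
    sinusoid_matrix,
)


def series(temps, start_year=1980, ice=None):
    temps = np.asarray(temps, dtype=float)
    years = np.arange(start_year, start_year + temps.shape[0])
    return MonthlyTemperatureSeries(years, temps, ice)


class TestMonthlyTrend:
    def test_exact_linear_series_recovers_slope(self, years42):
        temps = np.full((42, 12), 12.0)
        temps[:, 3] = 10 + 0.05 * (years42 - 1980)
        s = MonthlyTemperatureSeries(years42, temps)
        assert fit_monthly_trend(s, 4) == pytest.approx(0.05, abs=1e-12)

    def test_constant_series_has_zero_trend(self):
        s = series(np.full((42, 12), 12.0))
        assert fit_monthly_trend(s, 4) == pytest.approx(0.0, abs=1e-13)

    def test_matches_normal_equations_oracle_on_noisy_series(self, years42):
        rng = np.random.default_rng(7)
        temps = np.full((42, 12), 10.0)
        temps[:, 3] = 8 + 0.03 * (years42 - 1980) + rng.normal(0, 0.5, 42)
        s = MonthlyTemperatureSeries(years42, temps)
        expected = ols_slope_oracle(years42, temps[:, 3])
        assert fit_monthly_trend(s, 4) == pytest.approx(expected, rel=1e-10)

    def test_missing_years_are_dropped_pairwise(self, years42):
        rng = np.random.default_rng(11)
        temps = np.full((42, 12), 10.0)
        temps[:, 3] = 8 + 0.03 * (years42 - 1980) + rng.normal(0, 0.5, 42)
        temps[[2, 9, 30], 3] = np.nan
        s = MonthlyTemperatureSeries(years42, temps)
        keep = np.isfinite(temps[:, 3])
        expected = ols_slope_oracle(years42[keep], temps[keep, 3])
        assert fit_monthly_trend(s, 4) == pytest.approx(expected, rel=1e-10)

    def test_fewer_than_three_values_is_insufficient(self):
        temps = np.full((5, 12), np.nan)
        temps[:2, 3] = [10.0, 11.0]
        temps[:, 0] = 5.0  # keep rows non-empty
        with pytest.raises(InsufficientDataError):
            fit_monthly_trend(series(temps), 4)

    def test_month_index_out_of_range(self):
        with pytest.raises(ValueError):
            fit_monthly_trend(series(np.zeros((5, 12))), 13)


class TestSeasonalRateOfChange:
    def test_half_difference_of_flanking_months(self):
        temps = np.zeros((10, 12))
        temps[:, 2] = 5.0  # March
        temps[:, 4] = 11.0  # May
        assert seasonal_rate_of_change(series(temps), 4) == pytest.approx(3.0)

    def test_symmetric_peak_gives_zero_gradient(self):
        temps = np.zeros((10, 12))
        temps[:, 2] = 8.0
        temps[:, 4] = 8.0
        assert seasonal_rate_of_change(series(temps), 4) == pytest.approx(0.0)

    @pytest.mark.parametrize("month", range(1, 13))
    def test_sinusoid_gradient_matches_central_difference_closed_form(self, month):
        # central difference of a sinusoid: (S(m+1) - S(m-1))/2
        #   = A·sin(2π/12)·cos(θ_m)/... with sin(30°) = 0.5 -> 0.5·A·cos θ_m
        amplitude = 10.0
        s = series(sinusoid_matrix(n_years=10, amplitude=amplitude, mean=0.0))
        expected = 0.5 * amplitude * np.cos(month_phase(month))
        assert seasonal_rate_of_change(s, month) == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_december_window_wraps_into_next_january(self):
        # Nov of year y pairs with Jan of year y+1; last December dropped
        rng = np.random.default_rng(3)
        temps = rng.normal(10, 2, size=(6, 12))
        s = series(temps)
        by_hand = np.mean(
            [(temps[y + 1, 0] - temps[y, 10]) / 2 for y in range(5)]
        )
        assert seasonal_rate_of_change(s, 12) == pytest.approx(by_hand, rel=1e-12)

    def test_january_window_wraps_into_previous_december(self):
        rng = np.random.default_rng(4)
        temps = rng.normal(10, 2, size=(6, 12))
        s = series(temps)
        by_hand = np.mean(
            [(temps[y, 1] - temps[y - 1, 11]) / 2 for y in range(1, 6)]
        )
        assert seasonal_rate_of_change(s, 1) == pytest.approx(by_hand, rel=1e-12)

    def test_too_few_year_pairs_is_insufficient(self):
        temps = np.full((10, 12), np.nan)
        temps[:, 3] = 10.0
        temps[:2, 2] = 5.0
        temps[:2, 4] = 9.0
        with pytest.raises(InsufficientDataError):
            seasonal_rate_of_change(series(temps), 4)


class TestComputeShift:
    def test_unit_conversion_is_exact(self):
        assert compute_shift(0.1, 1.0) == 0.1 * 304.375
        assert compute_shift(1.0, 1.0) == 304.375
        assert MONTH_PER_YEAR_TO_DAYS_PER_DECADE == 304.375

    def test_zero_trend_means_zero_shift(self):
        assert compute_shift(0.0, 2.0) == 0.0

    def test_delayed_season_has_negative_shift(self):
        assert compute_shift(0.05, -1.25) == pytest.approx(-12.175, abs=1e-12)

    def test_zero_gradient_raises_instead_of_infinity(self):
        with pytest.raises(UndefinedShiftError):
            compute_shift(0.1, 0.0)

    @given(
        trend=st.floats(-5, 5, allow_nan=False),
        gradient=st.floats(0.5, 10.0),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    @settings(derandomize=True)
    def test_antisymmetry_in_the_trend(self, trend, gradient, sign):
        g = sign * gradient
        assert compute_shift(-trend, g) == -compute_shift(trend, g)

    @given(
        trend=st.floats(-5, 5, allow_nan=False),
        gradient=st.floats(0.5, 10.0),
        k=st.floats(0.01, 100.0),
    )
    @settings(derandomize=True)
    def test_scale_invariance_of_the_ratio(self, trend, gradient, k):
        assert compute_shift(k * trend, k * gradient) == pytest.approx(
            compute_shift(trend, gradient), rel=1e-12, abs=1e-12
        )


class TestShiftForSeason:
    def test_zero_trend_strong_seasonality_is_valid_with_zero_shift(self):
        s = series(sinusoid_matrix())
        res = shift_for_season(s, season_for("spring", "north"))
        assert res.valid
        assert res.exclusion_reason is ExclusionReason.NONE
        assert res.shift == pytest.approx(0.0, abs=1e-9)
        # consistency of the stored pieces
        assert res.shift == res.trend / res.gradient * MONTH_PER_YEAR_TO_DAYS_PER_DECADE

    def test_ice_in_41_of_42_years_excludes_location(self):
        temps = sinusoid_matrix()
        ice = np.zeros((42, 12), dtype=bool)
        ice[:41, 3] = True  # centre month of NH spring, 97.6% of years
        res = shift_for_season(series(temps, ice=ice), season_for("spring", "north"))
        assert not res.valid
        assert res.exclusion_reason is ExclusionReason.ICE_COVERED
        assert np.isnan(res.shift)

    def test_ice_in_37_of_42_years_is_retained(self):
        temps = sinusoid_matrix()
        ice = np.zeros((42, 12), dtype=bool)
        ice[:37, 3] = True  # 88.1% < 90%
        res = shift_for_season(series(temps, ice=ice), season_for("spring", "north"))
        assert res.valid

    def test_ice_rule_counts_any_month_of_the_window(self):
        temps = sinusoid_matrix()
        ice = np.zeros((42, 12), dtype=bool)
        ice[:, 2] = True  # March only, every year
        s = series(temps, ice=ice)
        assert ice_year_fraction(s, season_for("spring", "north")) == 1.0
        res = shift_for_season(s, season_for("spring", "north"))
        assert res.exclusion_reason is ExclusionReason.ICE_COVERED

    def test_pure_phase_drift_matches_analytic_estimator_value(self):
        # noise-free drift of 1 day/yr: the statistic's value has a
        # known closed form (finite-difference linearization included)
        s = series(sinusoid_matrix(drift=1.0))
        expected = drift_estimator_value(1.0, 42)
        for season in moving_windows():
            if season.centre_month in (1, 12):
                continue  # year-wrap windows drop a year
            res = shift_for_season(s, season)
            if res.valid:
                assert res.shift == pytest.approx(expected, rel=1e-9)

    def test_small_phase_drift_recovered_within_linearization_error(self):
        # at 0.25 day/yr the finite-difference bias stays below 5%
        drift = 0.25
        s = series(sinusoid_matrix(drift=drift))
        res = shift_for_season(s, season_for("summer", "north"))
        assert res.valid
        assert abs(res.shift - 10 * drift) / (10 * drift) < 0.05

    def test_drift_recovery_bias_shrinks_with_drift(self):
        errors = []
        for drift in (1.0, 0.5, 0.25):
            s = series(sinusoid_matrix(drift=drift))
            res = shift_for_season(s, season_for("summer", "north"))
            errors.append(abs(res.shift - 10 * drift) / (10 * drift))
        assert errors[0] > errors[1] > errors[2]

    def test_low_seasonality_keeps_trend_and_gradient(self):
        temps = np.zeros((42, 12))
        temps[:, 2] = 5.0
        temps[:, 4] = 5.8  # gradient 0.4 < 0.5
        res = shift_for_season(series(temps), season_for("spring", "north"))
        assert res.exclusion_reason is ExclusionReason.LOW_SEASONALITY
        assert res.gradient == pytest.approx(0.4)
        assert np.isnan(res.shift)

    def test_gradient_exactly_at_threshold_is_retained(self):
        temps = np.zeros((42, 12))
        temps[:, 2] = 5.0
        temps[:, 4] = 6.0  # gradient exactly 0.5
        res = shift_for_season(series(temps), season_for("spring", "north"))
        assert res.valid

    def test_negative_gradient_passes_magnitude_criterion(self):
        # autumn: lake cooling, gradient negative but seasonality strong
        s = series(sinusoid_matrix(trend=0.03))
        res = shift_for_season(s, season_for("autumn", "north"))
        assert res.valid
        assert res.gradient < -0.5
        assert res.shift < 0  # warming in a cooling season = delay

    def test_excess_missing_centre_month_is_insufficient(self):
        temps = sinusoid_matrix()
        temps[:12, 3] = np.nan  # 28.6% > 25%
        res = shift_for_season(series(temps), season_for("spring", "north"))
        assert res.exclusion_reason is ExclusionReason.INSUFFICIENT_DATA

    def test_ice_takes_precedence_over_other_exclusions(self):
        temps = np.zeros((42, 12))  # flat: would be low-seasonality
        ice = np.ones((42, 12), dtype=bool)
        res = shift_for_season(series(temps, ice=ice), season_for("spring", "north"))
        assert res.exclusion_reason is ExclusionReason.ICE_COVERED

    @given(offset=st.floats(-30, 30, allow_nan=False))
    @settings(derandomize=True, max_examples=25)
    def test_constant_offset_changes_nothing(self, offset):
        base = sinusoid_matrix(trend=0.02)
        r0 = shift_for_season(series(base), season_for("spring", "north"))
        r1 = shift_for_season(series(base + offset), season_for("spring", "north"))
        assert r1.trend == pytest.approx(r0.trend, rel=1e-9, abs=1e-12)
        assert r1.gradient == pytest.approx(r0.gradient, rel=1e-9)
        assert r1.shift == pytest.approx(r0.shift, rel=1e-8)


class TestSeriesValidation:
    def test_kelvin_input_is_converted_on_construction(self):
        base = sinusoid_matrix(trend=0.02)
        r_c = shift_for_season(series(base), season_for("spring", "north"))
        r_k = shift_for_season(series(base + 273.15), season_for("spring", "north"))
        assert r_k.shift == pytest.approx(r_c.shift, rel=1e-6)

    def test_noncontiguous_years_rejected(self):
        with pytest.raises(ValueError):
            MonthlyTemperatureSeries(np.array([2000, 2002, 2003]), np.zeros((3, 12)))

    def test_wrong_month_count_rejected(self):
        with pytest.raises(ValueError):
            MonthlyTemperatureSeries(np.arange(2000, 2003), np.zeros((3, 11)))

    def test_infinite_temperatures_rejected(self):
        temps = np.zeros((3, 12))
        temps[0, 0] = np.inf
        with pytest.raises(ValueError):
            MonthlyTemperatureSeries(np.arange(2000, 2003), temps)

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            ExclusionCriteria(gradient_threshold=0.0)
        with pytest.raises(ValueError):
            ExclusionCriteria(ice_year_fraction=1.5)
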