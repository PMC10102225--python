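"""The seasonal-shift statistic for monthly lake surface temperature.

The pace at which a seasonal temperature regime moves through the
calendar is estimated, for a chosen 3-month season, as the ratio of two
rates:

* the long-term linear trend of the season's centre-month temperature
  (°C yr⁻¹), and
* the climatological seasonal rate of change around that month
  (°C month⁻¹), computed as half the difference between the following
  and preceding months' temperatures, averaged over all years.

The ratio is in months per year and converts to days per decade by
multiplying by 10 years × 365.25 days yr⁻¹ / 12 months.  A positive
shift means the season's temperatures now arrive earlier in the year
(the season has advanced); a negative shift means they arrive later
(delayed).

Locations are excluded when the season is persistently ice covered,
when too much of the record is missing, or when the seasonal gradient
is too weak for the ratio to be meaningful (|gradient| below a
threshold, 0.5 °C month⁻¹ by default — characteristic of tropical lakes
with minimal seasonality).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seasons import SeasonDefinition

logger = logging.getLogger(__name__)

#: days decade⁻¹ equivalent of a shift of 1 month yr⁻¹ (10 × 365.25 / 12).
MONTH_PER_YEAR_TO_DAYS_PER_DECADE = 10.0 * 365.25 / 12.0

KELVIN_OFFSET = 273.15
#: water temperatures above this are only plausible on the Kelvin scale
KELVIN_DETECTION_THRESHOLD = 150.0


class InsufficientDataError(ValueError):
    """Too few usable values to estimate a trend or gradient."""


class UndefinedShiftError(ZeroDivisionError):
    """The seasonal gradient is zero, so the shift ratio is undefined."""


class ExclusionReason(enum.IntEnum):
    """Why a location was left out of the analysis.

    Integer codes are part of the on-disk contract (NetCDF / table
    exports) and must stay stable across versions.
    """

    NONE = 0
    ICE_COVERED = 1
    INSUFFICIENT_DATA = 2
    LOW_SEASONALITY = 3


@dataclass(frozen=True)
class ExclusionCriteria:
    """Thresholds deciding which locations enter the analysis.

    Parameters
    ----------
    gradient_threshold
        Minimum |seasonal gradient| in °C month⁻¹; locations below it
        are excluded as low-seasonality.  A gradient exactly at the
        threshold is retained.
    ice_year_fraction
        A location is excluded as ice covered when at least this
        fraction of years has ice in any month of the season window.
    max_missing_fraction
        Maximum tolerated fraction of missing centre-month values
        before a location is marked insufficient-data.
    min_years
        Minimum number of usable values (trend) or year pairs
        (gradient).
    """

    gradient_threshold: float = 0.5
    ice_year_fraction: float = 0.90
    max_missing_fraction: float = 0.25
    min_years: int = 3

    def __post_init__(self) -> None:
        if not self.gradient_threshold > 0:
            raise ValueError("gradient_threshold must be > 0")
        if not 0 < self.ice_year_fraction <= 1:
            raise ValueError("ice_year_fraction must be in (0, 1]")
        if not 0 <= self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in [0, 1)")
        if self.min_years < 3:
            raise ValueError("min_years must be at least 3")


@dataclass
class MonthlyTemperatureSeries:
    """One location's year × month mean surface water temperatures.

    ``temps`` is an ``(n_years, 12)`` float array in °C with NaN for
    missing months; ``ice`` is an optional boolean matrix of the same
    shape flagging months with ice cover.  Years must be contiguous and
    strictly increasing.  Kelvin input is detected (all finite values
    above 150) and converted on construction.
    """

    years: np.ndarray
    temps: np.ndarray
    ice: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.temps = np.array(self.temps, dtype=float)
        if self.temps.ndim != 2 or self.temps.shape[1] != 12:
            raise ValueError("temps must be a (n_years, 12) matrix")
        if self.years.ndim != 1 or len(self.years) != self.temps.shape[0]:
            raise ValueError("years must align with the rows of temps")
        if len(self.years) >= 2 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be strictly increasing and contiguous")
        finite = np.isfinite(self.temps)
        if np.any(np.isinf(self.temps)):
            raise ValueError("temperatures must be finite where not missing")
        if finite.any() and np.nanmin(self.temps) > KELVIN_DETECTION_THRESHOLD:
            logger.warning("temperatures look like Kelvin; converting to °C")
            self.temps = self.temps - KELVIN_OFFSET
        if self.ice is not None:
            self.ice = np.asarray(self.ice, dtype=bool)
            if self.ice.shape != self.temps.shape:
                raise ValueError("ice must have the same shape as temps")

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class ShiftResult:
    """Seasonal-shift estimate for one location and season.

    ``shift`` is in days decade⁻¹ (NaN when invalid); ``trend`` in
    °C yr⁻¹ and ``gradient`` in °C month⁻¹ are reported where they were
    computed (NaN when the location was excluded before estimation).
    """

    trend: float
    gradient: float
    shift: float
    valid: bool
    exclusion_reason: ExclusionReason


def fit_monthly_trend(series: MonthlyTemperatureSeries, month: int) -> float:
    """Ordinary-least-squares trend (°C yr⁻¹) of one calendar month.

    Regresses the given month's temperature on calendar year; missing
    years are dropped pairwise.  Requires at least three non-missing
    values.
    """
    _check_month(month)
    y = series.temps[:, month - 1]
    mask = np.isfinite(y)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"month {month}: {int(mask.sum())} non-missing values, need >= 3"
        )
    res = stats.linregress(series.years[mask].astype(float), y[mask])
    return float(res.slope)


def _adjacent_months(temps: np.ndarray, centre_month: int):
    """Per-year (preceding, following) month values around a centre.

    January and December centres wrap into the adjacent calendar year:
    a December-centred window pairs November of year y with January of
    year y + 1 (the final year is dropped), and a January-centred
    window pairs December of year y − 1 with February of year y.
    """
    m = centre_month
    if m == 1:
        return temps[:-1, 11], temps[1:, 1]
    if m == 12:
        return temps[:-1, 10], temps[1:, 0]
    return temps[:, m - 2], temps[:, m]


def seasonal_rate_of_change(
    series: MonthlyTemperatureSeries, centre_month: int
) -> float:
    """Climatological seasonal rate of change (°C month⁻¹).

    Half the difference between the month following and the month
    preceding ``centre_month``, averaged over all years with both
    months present.  Positive while the lake is warming through the
    season, negative while cooling.
    """
    _check_month(centre_month)
    prec, foll = _adjacent_months(series.temps, centre_month)
    half_diff = (foll - prec) / 2.0
    ok = np.isfinite(half_diff)
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"centre month {centre_month}: {int(ok.sum())} year pairs, need >= 3"
        )
    return float(half_diff[ok].mean())


def compute_shift(trend: float, gradient: float) -> float:
    """Convert a trend/gradient pair to a shift in days decade⁻¹.

    Raises
    ------
    UndefinedShiftError
        If the gradient is exactly zero (never silently returns an
        infinite shift).
    """
    if gradient == 0:
        raise UndefinedShiftError("seasonal gradient is zero; shift undefined")
    return (trend / gradient) * MONTH_PER_YEAR_TO_DAYS_PER_DECADE


def ice_year_fraction(series: MonthlyTemperatureSeries, season: SeasonDefinition) -> float:
    """Fraction of years with ice cover in any month of the season window.

    Window months that wrap the year boundary follow the same
    year-alignment as the gradient (December-centred windows look at
    January of the following year).  Returns 0.0 when the series has no
    ice information.
    """
    if series.ice is None:
        return 0.0
    n = series.n_years
    affected = np.zeros(n, dtype=bool)
    centre = season.centre_month
    for w in season.window:
        if centre == 12 and w == 1:
            affected[:-1] |= series.ice[1:, 0]
        elif centre == 1 and w == 12:
            affected[1:] |= series.ice[:-1, 11]
        else:
            affected |= series.ice[:, w - 1]
    return float(affected.mean())


def shift_for_season(
    series: MonthlyTemperatureSeries,
    season: SeasonDefinition,
    criteria: ExclusionCriteria | None = None,
) -> ShiftResult:
    """Full per-location seasonal-shift estimate with exclusion rules.

    Exclusions are evaluated in a fixed order: ice cover, then data
    completeness, then the low-seasonality criterion.  The seasonality
    criterion is applied to the absolute gradient (autumn gradients are
    negative); a gradient exactly at the threshold is retained.
    """
    if criteria is None:
        criteria = ExclusionCriteria()

    if ice_year_fraction(series, season) >= criteria.ice_year_fraction:
        return ShiftResult(np.nan, np.nan, np.nan, False, ExclusionReason.ICE_COVERED)

    centre = season.centre_month
    centre_vals = series.temps[:, centre - 1]
    missing_frac = float(np.isnan(centre_vals).mean())
    if missing_frac > criteria.max_missing_fraction:
        return ShiftResult(
            np.nan, np.nan, np.nan, False, ExclusionReason.INSUFFICIENT_DATA
        )
    try:
        trend = fit_monthly_trend(series, centre)
        gradient = seasonal_rate_of_change(series, centre)
    except InsufficientDataError:
        return ShiftResult(
            np.nan, np.nan, np.nan, False, ExclusionReason.INSUFFICIENT_DATA
        )

    if abs(gradient) < criteria.gradient_threshold:
        return ShiftResult(
            trend, gradient, np.nan, False, ExclusionReason.LOW_SEASONALITY
        )
    return ShiftResult(
        trend, gradient, compute_shift(trend, gradient), True, ExclusionReason.NONE
    )


def _check_month(month: int) -> None:
    if not 1 <= month <= 12:
        raise ValueError(f"month index must be in 1..12, got {month}")
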