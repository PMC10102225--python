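"""Grid-scale application of the seasonal-shift statistic.

This module applies the per-location statistic over whole latitude ×
longitude grids with a vectorised implementation that is numerically
identical to looping :func:`lakeshift.core_stats.shift_for_season` over
cells, and builds the derived products: summer lengthening (summer
shift minus autumn shift), ensemble means over lake-model × climate-model
members, and regional summaries (median and interquartile range over
valid locations — medians because per-lake shift distributions are
strongly skewed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core_stats import (
    MONTH_PER_YEAR_TO_DAYS_PER_DECADE,
    ExclusionCriteria,
    ExclusionReason,
    MonthlyTemperatureSeries,
)
from .seasons import SeasonDefinition, hemisphere_of, season_for

logger = logging.getLogger(__name__)

RegionPredicate = Callable[[float, float], bool]


class EmptyRegionError(ValueError):
    """A summary was requested over a region with no valid locations."""


@dataclass
class TemperatureGrid:
    """Gridded monthly temperatures: shape (n_years, 12, n_lat, n_lon).

    ``temps`` is in °C with NaN for missing months; ``ice`` is an
    optional boolean array of the same shape.
    """

    lats: np.ndarray
    lons: np.ndarray
    years: np.ndarray
    temps: np.ndarray
    ice: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.temps = np.asarray(self.temps, dtype=float)
        expected = (len(self.years), 12, len(self.lats), len(self.lons))
        if self.temps.shape != expected:
            raise ValueError(
                f"temps shape {self.temps.shape} != (n_years, 12, n_lat, n_lon) {expected}"
            )
        if len(self.years) >= 2 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be strictly increasing and contiguous")
        if self.ice is not None:
            self.ice = np.asarray(self.ice, dtype=bool)
            if self.ice.shape != self.temps.shape:
                raise ValueError("ice must have the same shape as temps")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lats), len(self.lons))

    @property
    def n_cells(self) -> int:
        return len(self.lats) * len(self.lons)

    def series_at(self, i: int, j: int) -> MonthlyTemperatureSeries:
        """Extract the single-location series for grid cell (i, j)."""
        ice = self.ice[:, :, i, j] if self.ice is not None else None
        return MonthlyTemperatureSeries(self.years, self.temps[:, :, i, j], ice)


@dataclass
class ShiftMap:
    """Georeferenced field of seasonal-shift results for one season.

    All 2-D arrays are (n_lat, n_lon).  ``reason`` holds the integer
    codes of :class:`~lakeshift.core_stats.ExclusionReason`; ``shift``,
    ``trend`` and ``gradient`` are NaN where not computed.
    ``centre_month`` is None for maps merged across hemispheres or
    derived by differencing seasons.
    """

    lats: np.ndarray
    lons: np.ndarray
    shift: np.ndarray
    trend: np.ndarray
    gradient: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    season_name: str
    centre_month: int | None = None
    member: str = "observed"

    def __post_init__(self) -> None:
        shape = (len(self.lats), len(self.lons))
        for name in ("shift", "trend", "gradient", "valid", "reason"):
            arr = getattr(self, name)
            if np.asarray(arr).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
        self.valid = np.asarray(self.valid, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=np.int8)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def exclusion_counts(self) -> dict[str, int]:
        """Tally of locations per exclusion reason (valid included)."""
        return {
            reason.name.lower(): int((self.reason == reason).sum())
            for reason in ExclusionReason
        }


@dataclass(frozen=True)
class SummaryStats:
    """Median and interquartile range of shifts over valid locations."""

    median: float
    q25: float
    q75: float
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("SummaryStats requires n > 0")
        if not (self.q25 <= self.median <= self.q75):
            raise ValueError("quantiles must satisfy q25 <= median <= q75")


def _ols_slope_grid(years: np.ndarray, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell OLS slope of vals (Y, La, Lo) on years, NaN-aware.

    Returns (slope, count of non-missing values).  Cells with < 2
    usable points get NaN.
    """
    mask = np.isfinite(vals)
    n = mask.sum(axis=0)
    x = years.astype(float)[:, None, None]
    xw = np.where(mask, x, 0.0)
    yw = np.where(mask, vals, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = xw.sum(axis=0) / n
        ybar = yw.sum(axis=0) / n
        dx = np.where(mask, x - xbar, 0.0)
        dy = np.where(mask, vals - ybar, 0.0)
        sxx = (dx * dx).sum(axis=0)
        sxy = (dx * dy).sum(axis=0)
        slope = sxy / sxx
    slope = np.where(n >= 2, slope, np.nan)
    return slope, n


def _gradient_grid(temps: np.ndarray, centre_month: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell climatological gradient for temps (Y, 12, La, Lo).

    Mirrors the year alignment of the scalar path: January/December
    centres wrap into the adjacent calendar year.
    """
    m = centre_month
    if m == 1:
        prec, foll = temps[:-1, 11], temps[1:, 1]
    elif m == 12:
        prec, foll = temps[:-1, 10], temps[1:, 0]
    else:
        prec, foll = temps[:, m - 2], temps[:, m]
    half_diff = (foll - prec) / 2.0
    ok = np.isfinite(half_diff)
    npairs = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grad = np.where(ok, half_diff, 0.0).sum(axis=0) / npairs
    grad = np.where(npairs >= 1, grad, np.nan)
    return grad, npairs


def _ice_fraction_grid(grid: TemperatureGrid, season: SeasonDefinition) -> np.ndarray:
    """Per-cell fraction of years with ice in any month of the window."""
    if grid.ice is None:
        return np.zeros(grid.shape)
    n = len(grid.years)
    affected = np.zeros((n,) + grid.shape, dtype=bool)
    centre = season.centre_month
    for w in season.window:
        if centre == 12 and w == 1:
            affected[:-1] |= grid.ice[1:, 0]
        elif centre == 1 and w == 12:
            affected[1:] |= grid.ice[:-1, 11]
        else:
            affected |= grid.ice[:, w - 1]
    return affected.mean(axis=0)


def compute_grid_shifts(
    grid: TemperatureGrid,
    season: SeasonDefinition,
    criteria: ExclusionCriteria | None = None,
    member: str = "observed",
) -> ShiftMap:
    """Apply the seasonal-shift statistic to every grid cell.

    Vectorised, but cell-for-cell equivalent to calling
    :func:`lakeshift.core_stats.shift_for_season` on each location's
    series.  Exclusion reasons are evaluated in the order ice cover →
    insufficient data → low seasonality and preserved per cell.
    """
    if criteria is None:
        criteria = ExclusionCriteria()
    if grid.n_cells == 0:
        raise ValueError("grid has no cells")

    m = season.centre_month
    centre_vals = grid.temps[:, m - 1]
    trend, n_trend = _ols_slope_grid(grid.years, centre_vals)
    gradient, n_pairs = _gradient_grid(grid.temps, m)
    missing_frac = np.isnan(centre_vals).mean(axis=0)
    ice_frac = _ice_fraction_grid(grid, season)

    with np.errstate(invalid="ignore"):
        low_seas = np.abs(gradient) < criteria.gradient_threshold
    insufficient = (
        (missing_frac > criteria.max_missing_fraction)
        | (n_trend < criteria.min_years)
        | (n_pairs < criteria.min_years)
    )
    ice_excluded = ice_frac >= criteria.ice_year_fraction

    reason = np.zeros(grid.shape, dtype=np.int8)
    reason[low_seas] = ExclusionReason.LOW_SEASONALITY
    reason[insufficient] = ExclusionReason.INSUFFICIENT_DATA
    reason[ice_excluded] = ExclusionReason.ICE_COVERED
    valid = reason == ExclusionReason.NONE

    # match the scalar path: trend/gradient only reported where estimation ran
    estimated = ~(ice_excluded | insufficient)
    trend = np.where(estimated, trend, np.nan)
    gradient = np.where(estimated, gradient, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        shift = np.where(valid, (trend / gradient) * MONTH_PER_YEAR_TO_DAYS_PER_DECADE, np.nan)

    return ShiftMap(
        lats=grid.lats,
        lons=grid.lons,
        shift=shift,
        trend=trend,
        gradient=gradient,
        valid=valid,
        reason=reason,
        season_name=season.name,
        centre_month=season.centre_month,
        member=member,
    )


def compute_hemispheric_shifts(
    grid: TemperatureGrid,
    season_name: str,
    criteria: ExclusionCriteria | None = None,
    member: str = "observed",
) -> ShiftMap:
    """One named season over a possibly hemisphere-spanning grid.

    Each cell uses its own hemisphere's window (e.g. spring is
    March–May north of the equator and September–November south of it);
    the two hemispheric maps are merged by latitude sign.
    """
    north = compute_grid_shifts(grid, season_for(season_name, "north"), criteria, member)
    south = compute_grid_shifts(grid, season_for(season_name, "south"), criteria, member)
    is_north = (grid.lats >= 0)[:, None]

    def pick(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.where(is_north, a, b)

    hemis = {hemisphere_of(lat) for lat in grid.lats}
    centre = None
    if len(hemis) == 1:
        centre = season_for(season_name, hemis.pop()).centre_month
    return ShiftMap(
        lats=grid.lats,
        lons=grid.lons,
        shift=pick(north.shift, south.shift),
        trend=pick(north.trend, south.trend),
        gradient=pick(north.gradient, south.gradient),
        valid=pick(north.valid, south.valid),
        reason=pick(north.reason, south.reason),
        season_name=season_name,
        centre_month=centre,
        member=member,
    )


def _check_same_locations(a: ShiftMap, b: ShiftMap) -> None:
    if a.shift.shape != b.shift.shape or not (
        np.allclose(a.lats, b.lats) and np.allclose(a.lons, b.lons)
    ):
        raise ValueError("maps cover different locations")


def summer_length_change(summer: ShiftMap, autumn: ShiftMap) -> ShiftMap:
    """Change in summer-season duration: summer shift minus autumn shift.

    An advance of summer (positive) combined with a delay of autumn
    (negative) lengthens the summer-temperature period, so the
    difference equals the sum of the advance and the delay.  A location
    is valid only where both input seasons are valid; otherwise it
    inherits the first invalid input's exclusion reason (summer's
    first).
    """
    _check_same_locations(summer, autumn)
    if summer.member != autumn.member:
        raise ValueError("summer and autumn maps come from different members")
    both = summer.valid & autumn.valid
    length = np.where(both, summer.shift - autumn.shift, np.nan)
    reason = np.where(
        both,
        np.int8(ExclusionReason.NONE),
        np.where(~summer.valid, summer.reason, autumn.reason),
    )
    nan2 = np.full(summer.shift.shape, np.nan)
    return ShiftMap(
        lats=summer.lats,
        lons=summer.lons,
        shift=length,
        trend=nan2,
        gradient=nan2.copy(),
        valid=both,
        reason=reason,
        season_name="summer_length",
        centre_month=None,
        member=summer.member,
    )


def ensemble_average(members: Sequence[ShiftMap]) -> ShiftMap:
    """Mean shift across ensemble members, computed per location.

    The statistic is computed independently per member and then
    averaged over the members where the location is valid.  A location
    is valid in the output when it is valid in at least half of the
    members; invalid output locations carry the most common exclusion
    reason among the invalid members (ties broken toward ice cover).
    Member order does not affect the result.
    """
    if len(members) == 0:
        raise ValueError("ensemble must contain at least one member")
    first = members[0]
    for other in members[1:]:
        _check_same_locations(first, other)
        if other.season_name != first.season_name:
            raise ValueError("ensemble members cover different seasons")
    n_members = len(members)

    validity = np.stack([m.valid for m in members])
    n_valid = validity.sum(axis=0)
    out_valid = n_valid >= n_members / 2.0

    def mean_over_valid(stack: np.ndarray) -> np.ndarray:
        # sort member values per location before summing so the result
        # is bit-identical under any permutation of the member list
        vals = np.sort(np.where(validity, stack, np.nan), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.nansum(vals, axis=0) / n_valid
        return np.where(out_valid & (n_valid > 0), out, np.nan)

    shifts = mean_over_valid(np.stack([m.shift for m in members]))
    trends = mean_over_valid(np.stack([m.trend for m in members]))
    gradients = mean_over_valid(np.stack([m.gradient for m in members]))

    reasons = np.stack([m.reason for m in members])
    counts = np.stack(
        [(reasons == code).sum(axis=0) for code in (1, 2, 3)]
    )  # order fixes the tie-break: ice < insufficient < low seasonality
    modal = (np.argmax(counts, axis=0) + 1).astype(np.int8)
    reason = np.where(out_valid, np.int8(ExclusionReason.NONE), modal)

    return ShiftMap(
        lats=first.lats,
        lons=first.lons,
        shift=shifts,
        trend=trends,
        gradient=gradients,
        valid=out_valid,
        reason=reason,
        season_name=first.season_name,
        centre_month=first.centre_month,
        member=f"ensemble_mean[{n_members}]",
    )


def region_mask(smap: ShiftMap, region: RegionPredicate | np.ndarray | None) -> np.ndarray:
    """Resolve a region spec (predicate, boolean mask or None) to a mask."""
    if region is None:
        return np.ones(smap.shift.shape, dtype=bool)
    if callable(region):
        lat2, lon2 = np.meshgrid(smap.lats, smap.lons, indexing="ij")
        vec = np.vectorize(region, otypes=[bool])
        return vec(lat2, lon2)
    mask = np.asarray(region, dtype=bool)
    if mask.shape != smap.shift.shape:
        raise ValueError("region mask shape does not match the map")
    return mask


def hemisphere_mask(smap: ShiftMap, hemisphere: str) -> np.ndarray:
    """Boolean mask selecting one hemisphere (equator counted north)."""
    if hemisphere == "north":
        sel = smap.lats >= 0
    elif hemisphere == "south":
        sel = smap.lats < 0
    else:
        raise ValueError(f"unknown hemisphere: {hemisphere!r}")
    return np.broadcast_to(sel[:, None], smap.shift.shape).copy()


def summarize(
    smap: ShiftMap, region: RegionPredicate | np.ndarray | None = None
) -> SummaryStats:
    """Median and 25th/75th percentiles over a region's valid locations.

    Quantiles use linear interpolation between order statistics.

    Raises
    ------
    EmptyRegionError
        If the region contains no valid locations.
    """
    mask = region_mask(smap, region) & smap.valid
    vals = smap.shift[mask]
    if vals.size == 0:
        raise EmptyRegionError("no valid locations in the requested region")
    q25, med, q75 = np.percentile(vals, [25.0, 50.0, 75.0])
    return SummaryStats(median=float(med), q25=float(q25), q75=float(q75), n=int(vals.size))
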