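"""Reading and writing the standard formats the pipeline touches.

Gridded monthly temperature input/output is NetCDF with CF-style
``(time, lat, lon)`` layout, handled through xarray.  Shift maps are
written both as NetCDF (with shift, trend, gradient, validity and
integer exclusion-reason layers plus season/member metadata) and as
delimited tables (one row per location) for per-lake workflows.
Per-lake monthly series can also be read from long-format delimited
tables.

Conventions applied at ingest: Kelvin is converted to °C when declared
or detected (all values above 150), longitudes are normalised to
[−180, 180), descending latitude axes are flipped, and sub-monthly
time axes are averaged to calendar months, each with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .core_stats import (
    KELVIN_DETECTION_THRESHOLD,
    KELVIN_OFFSET,
    ExclusionReason,
    MonthlyTemperatureSeries,
)
from .pipeline import ShiftMap, TemperatureGrid

logger = logging.getLogger(__name__)

_NETCDF_ENGINE = "scipy"  # classic NetCDF3, universally readable


class GridLoadError(Exception):
    """Base class for dataset loading failures."""


class MissingVariableError(GridLoadError):
    """A declared variable is absent from the dataset."""


class TimeAxisError(GridLoadError):
    """The time coordinate cannot be resolved to (year, month)."""


class EmptyYearIntersectionError(GridLoadError):
    """The requested year range does not overlap the file's years."""


@dataclass
class DatasetHandle:
    """Where a gridded temperature dataset lives and how to read it.

    ``units`` may be "C", "K" or "auto" (detect Kelvin from the value
    range).
    """

    path: str | Path
    temp_var: str = "temp"
    ice_var: str | None = None
    time_name: str = "time"
    lat_name: str = "lat"
    lon_name: str = "lon"
    units: str = "auto"


def read_monthly_grid(
    handle: DatasetHandle, year_range: tuple[int, int] | None = None
) -> TemperatureGrid:
    """Load a NetCDF monthly temperature grid into a TemperatureGrid.

    Raises
    ------
    MissingVariableError, TimeAxisError, EmptyYearIntersectionError
        Distinct failures for absent variables, unusable time axes and
        a year range disjoint from the file.
    """
    with xr.open_dataset(handle.path) as ds:
        ds = ds.load()
    for var in filter(None, (handle.temp_var, handle.ice_var)):
        if var not in ds:
            raise MissingVariableError(
                f"variable {var!r} not found in {handle.path} "
                f"(has {sorted(ds.data_vars)})"
            )
    for coord in (handle.time_name, handle.lat_name, handle.lon_name):
        if coord not in ds.coords and coord not in ds.dims:
            raise MissingVariableError(f"coordinate {coord!r} not found in {handle.path}")

    try:
        years_all = ds[handle.time_name].dt.year.values
        months_all = ds[handle.time_name].dt.month.values
    except (TypeError, AttributeError) as exc:
        raise TimeAxisError(
            f"time coordinate {handle.time_name!r} is not resolvable to year/month"
        ) from exc

    da = ds[handle.temp_var].transpose(handle.time_name, handle.lat_name, handle.lon_name)
    vals = da.values.astype(float)
    ice_vals = None
    if handle.ice_var is not None:
        ice_vals = (
            ds[handle.ice_var]
            .transpose(handle.time_name, handle.lat_name, handle.lon_name)
            .values
        )

    lats = ds[handle.lat_name].values.astype(float)
    lons = ds[handle.lon_name].values.astype(float)

    # sub-monthly time axes: average duplicates into calendar months
    key = years_all.astype(np.int64) * 12 + (months_all - 1)
    if len(np.unique(key)) < len(key):
        logger.info("sub-monthly time axis in %s: averaging to calendar months", handle.path)
        order = np.argsort(key, kind="stable")
        key, vals = key[order], vals[order]
        if ice_vals is not None:
            ice_vals = ice_vals[order]
        uniq, inverse = np.unique(key, return_inverse=True)
        agg = np.full((len(uniq),) + vals.shape[1:], np.nan)
        ice_agg = np.zeros((len(uniq),) + vals.shape[1:], dtype=bool) if ice_vals is not None else None
        for k in range(len(uniq)):
            sel = inverse == k
            with np.errstate(invalid="ignore"):
                agg[k] = np.nanmean(vals[sel], axis=0)
            if ice_agg is not None:
                ice_agg[k] = np.any(ice_vals[sel].astype(bool), axis=0)
        key, vals, ice_vals = uniq, agg, ice_agg

    file_years = np.unique(key // 12)
    if year_range is not None:
        lo, hi = year_range
        file_years = file_years[(file_years >= lo) & (file_years <= hi)]
        if len(file_years) == 0:
            raise EmptyYearIntersectionError(
                f"requested years {year_range} do not intersect {handle.path}"
            )
    years = np.arange(file_years.min(), file_years.max() + 1)

    temps = np.full((len(years), 12, len(lats), len(lons)), np.nan)
    ice = (
        np.zeros((len(years), 12, len(lats), len(lons)), dtype=bool)
        if ice_vals is not None
        else None
    )
    for idx, k in enumerate(key):
        yi = int(k // 12) - int(years[0])
        if 0 <= yi < len(years):
            temps[yi, int(k % 12)] = vals[idx]
            if ice is not None:
                ice[yi, int(k % 12)] = np.asarray(ice_vals[idx], dtype=bool)

    if handle.units == "K" or (
        handle.units == "auto"
        and np.isfinite(temps).any()
        and np.nanmin(temps) > KELVIN_DETECTION_THRESHOLD
    ):
        logger.info("converting %s from Kelvin to °C", handle.path)
        temps = temps - KELVIN_OFFSET

    if len(lats) > 1 and lats[0] > lats[-1]:
        logger.info("descending latitude axis in %s: flipping", handle.path)
        lats = lats[::-1].copy()
        temps = temps[:, :, ::-1]
        if ice is not None:
            ice = ice[:, :, ::-1]

    norm_lons = ((lons + 180.0) % 360.0) - 180.0
    if not np.array_equal(norm_lons, lons):
        logger.info("normalising longitudes of %s to [-180, 180)", handle.path)
        order = np.argsort(norm_lons, kind="stable")
        lons = norm_lons[order]
        temps = temps[:, :, :, order]
        if ice is not None:
            ice = ice[:, :, :, order]

    return TemperatureGrid(lats=lats, lons=lons, years=years, temps=temps, ice=ice)


def write_monthly_grid(grid: TemperatureGrid, path: str | Path, temp_var: str = "temp") -> None:
    """Write a TemperatureGrid as CF-style NetCDF (°C, mid-month stamps)."""
    time = [
        pd.Timestamp(year=int(y), month=m, day=15)
        for y in grid.years
        for m in range(1, 13)
    ]
    n_time = len(time)
    shape = (n_time, len(grid.lats), len(grid.lons))
    data_vars = {
        temp_var: (
            ("time", "lat", "lon"),
            grid.temps.reshape(shape),
            {"units": "degC", "long_name": "monthly mean lake surface water temperature"},
        )
    }
    if grid.ice is not None:
        data_vars["ice"] = (
            ("time", "lat", "lon"),
            grid.ice.reshape(shape).astype(np.int8),
            {"long_name": "ice cover present this month", "flag_values": "0 1"},
        )
    ds = xr.Dataset(
        data_vars,
        coords={"time": time, "lat": grid.lats, "lon": grid.lons},
    )
    ds.to_netcdf(path, engine=_NETCDF_ENGINE)


_SEASON_ATTRS = ("season_name", "centre_month", "member")


def write_shift_map(smap: ShiftMap, path: str | Path) -> None:
    """Write a ShiftMap as NetCDF with all layers and metadata attrs.

    The exclusion-reason codes (0 none, 1 ice_covered,
    2 insufficient_data, 3 low_seasonality) are a stable contract.
    """
    ds = xr.Dataset(
        {
            "shift": (("lat", "lon"), smap.shift, {"units": "days per decade"}),
            "trend": (("lat", "lon"), smap.trend, {"units": "degC per year"}),
            "gradient": (("lat", "lon"), smap.gradient, {"units": "degC per month"}),
            "valid": (("lat", "lon"), smap.valid.astype(np.int8)),
            "reason": (
                ("lat", "lon"),
                smap.reason,
                {"flag_values": "0 1 2 3", "flag_meanings": "none ice_covered insufficient_data low_seasonality"},
            ),
        },
        coords={"lat": smap.lats, "lon": smap.lons},
        attrs={
            "season_name": smap.season_name,
            "centre_month": -1 if smap.centre_month is None else int(smap.centre_month),
            "member": smap.member,
        },
    )
    ds.to_netcdf(path, engine=_NETCDF_ENGINE)


def read_shift_map(path: str | Path) -> ShiftMap:
    """Round-trip counterpart of :func:`write_shift_map`."""
    with xr.open_dataset(path) as ds:
        ds = ds.load()
    centre = int(ds.attrs["centre_month"])
    return ShiftMap(
        lats=ds["lat"].values,
        lons=ds["lon"].values,
        shift=ds["shift"].values,
        trend=ds["trend"].values,
        gradient=ds["gradient"].values,
        valid=ds["valid"].values.astype(bool),
        reason=ds["reason"].values.astype(np.int8),
        season_name=str(ds.attrs["season_name"]),
        centre_month=None if centre < 0 else centre,
        member=str(ds.attrs["member"]),
    )


def shift_map_table(smap: ShiftMap) -> pd.DataFrame:
    """One row per location: lat, lon, shift, trend, gradient, reason."""
    lat2, lon2 = np.meshgrid(smap.lats, smap.lons, indexing="ij")
    return pd.DataFrame(
        {
            "lat": lat2.ravel(),
            "lon": lon2.ravel(),
            "shift": smap.shift.ravel(),
            "trend": smap.trend.ravel(),
            "gradient": smap.gradient.ravel(),
            "valid": smap.valid.ravel(),
            "reason": smap.reason.ravel(),
            "reason_name": [ExclusionReason(r).name.lower() for r in smap.reason.ravel()],
        }
    )


def write_shift_table(smap: ShiftMap, path: str | Path) -> None:
    """CSV export of :func:`shift_map_table`."""
    shift_map_table(smap).to_csv(path, index=False)


def read_lake_table(path: str | Path) -> dict[str, MonthlyTemperatureSeries]:
    """Per-lake monthly series from a long-format delimited table.

    Expected columns: ``year``, ``month``, ``temp``; optional ``lake``
    (identifier, defaults to a single unnamed lake) and ``ice`` (0/1).
    Kelvin input is converted on series construction.
    """
    df = pd.read_csv(path)
    for col in ("year", "month", "temp"):
        if col not in df.columns:
            raise MissingVariableError(f"column {col!r} not found in {path}")
    if "lake" not in df.columns:
        df = df.assign(lake="lake")
    out: dict[str, MonthlyTemperatureSeries] = {}
    for lake, sub in df.groupby("lake", sort=True):
        years = np.arange(int(sub["year"].min()), int(sub["year"].max()) + 1)
        temps = np.full((len(years), 12), np.nan)
        ice = np.zeros((len(years), 12), dtype=bool) if "ice" in sub.columns else None
        yi = sub["year"].to_numpy(int) - years[0]
        mi = sub["month"].to_numpy(int) - 1
        temps[yi, mi] = sub["temp"].to_numpy(float)
        if ice is not None:
            ice[yi, mi] = sub["ice"].to_numpy() != 0
        out[str(lake)] = MonthlyTemperatureSeries(years, temps, ice)
    return out
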