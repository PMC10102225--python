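"""Synthetic lake-temperature grids with known ground truth.

The generator emulates the statistical structure of gridded monthly
lake surface temperature products (reanalysis or lake-model ensembles):
a smooth sinusoidal annual cycle, an optional linear warming trend, an
optional phenological phase drift (the whole cycle translated earlier
each year), independent Gaussian observation noise, and seasonal ice
flags where the noiseless temperature falls below a freezing threshold.
Southern-hemisphere cells (negative latitude) carry the annual cycle
offset by six months.

The model temperature for year ``y`` and month ``m`` is

    T(y, m) = mean + A·sin(2π·(d_m + δ·(y − y₀)) / 365.25 + φ₀ + φ_h)
              + b·(y − y₀) + ε,

with ``d_m`` the mid-month day-of-year on a fixed 365.25-day calendar,
``δ`` the phase drift in days yr⁻¹ (positive = the cycle arrives
earlier), ``b`` the warming trend in °C yr⁻¹, ``φ_h`` 0 in the north
and π in the south, and ``ε ~ N(0, σ²)``.  The base phase ``φ₀``
anchors the northern thermal maximum at mid-August (minimum
mid-February): lake surface temperatures lag solar forcing, so the
maximum falls in late summer.  May is then the steepest climatological
rise — where the central-difference gradient equals 0.5·A exactly —
and November the steepest fall; all three fixed seasons keep a strong
gradient (spring +0.433·A, summer +0.25·A, autumn −0.433·A).  Monthly means are point
evaluations at mid-month rather than calendar-month integrals — an
adequate idealisation for testing a monthly-resolution statistic.

:func:`expected_shift` gives the closed-form shift this model implies,
so parameter-recovery tests need no numerical reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_stats import MONTH_PER_YEAR_TO_DAYS_PER_DECADE, UndefinedShiftError
from .pipeline import TemperatureGrid

DAYS_PER_YEAR = 365.25
MONTH_LENGTH_DAYS = DAYS_PER_YEAR / 12.0


def mid_month_day(month: int | np.ndarray) -> np.ndarray:
    """Mid-month day-of-year on the fixed 365.25-day calendar."""
    return (np.asarray(month, dtype=float) - 0.5) * MONTH_LENGTH_DAYS


#: base phase putting the northern seasonal maximum at mid-August
BASE_PHASE = np.pi / 2.0 - 2.0 * np.pi * float(mid_month_day(8)) / DAYS_PER_YEAR


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic climate.

    Defaults mirror the historic study conditions for gridded lake
    temperature: a 42-year record starting in 1980, a 10 °C seasonal
    amplitude around a 15 °C mean — strong mid-latitude seasonality —
    and no trend, drift or noise unless requested.

    ``phase_drift`` is in days yr⁻¹, positive when the annual cycle
    arrives earlier each year.  ``ice_threshold`` (°C) flags months
    whose noiseless temperature falls below it; None disables ice.
    ``ar1`` optionally adds lag-one autocorrelation to the noise along
    the month axis (off by default: the statistic assumes nothing
    about autocorrelation).
    """

    n_years: int = 42
    start_year: int = 1980
    mean_temp: float = 15.0
    amplitude: float = 10.0
    warming_trend: float = 0.0
    phase_drift: float = 0.0
    noise_sd: float = 0.0
    ice_threshold: float | None = None
    seed: int = 0
    grid_shape: tuple[int, int] = (1, 1)
    lat_range: tuple[float, float] = (35.0, 65.0)
    lon_range: tuple[float, float] = (-10.0, 10.0)
    ar1: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= abs(self.ar1) < 1:
            raise ValueError("ar1 must satisfy |ar1| < 1")
        n_lat, n_lon = self.grid_shape
        if n_lat < 1 or n_lon < 1:
            raise ValueError("grid_shape must be at least (1, 1)")


def _axis(lo: float, hi: float, n: int) -> np.ndarray:
    return np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])


def noiseless_field(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lats, lons, clean) with clean shaped (n_years, 12, n_lat, n_lon)."""
    n_lat, n_lon = spec.grid_shape
    lats = _axis(spec.lat_range[0], spec.lat_range[1], n_lat)
    lons = _axis(spec.lon_range[0], spec.lon_range[1], n_lon)
    dy = np.arange(spec.n_years, dtype=float)
    d_m = mid_month_day(np.arange(1, 13))
    phase_h = np.where(lats < 0, np.pi, 0.0)
    arg = (
        2.0 * np.pi
        * (d_m[None, :, None] + spec.phase_drift * dy[:, None, None])
        / DAYS_PER_YEAR
        + BASE_PHASE
        + phase_h[None, None, :]
    )
    clean = (
        spec.mean_temp
        + spec.amplitude * np.sin(arg)
        + spec.warming_trend * dy[:, None, None]
    )
    clean = np.broadcast_to(clean[:, :, :, None], (spec.n_years, 12, n_lat, n_lon))
    return lats, lons, np.ascontiguousarray(clean)


def generate(spec: SyntheticSpec) -> TemperatureGrid:
    """Generate a reproducible synthetic temperature grid.

    Noise is drawn from ``numpy.random.default_rng(spec.seed)``, so the
    same spec yields bitwise-identical output.  Ice flags come from the
    noiseless signal (observation noise should not flicker ice on and
    off), aligned to the same year × month cells as the temperatures.
    """
    lats, lons, clean = noiseless_field(spec)
    temps = clean.copy()
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        eps = rng.normal(0.0, spec.noise_sd, size=clean.shape)
        if spec.ar1 != 0.0:
            eps = _ar1_filter(eps, spec.ar1)
        temps = temps + eps
    ice = None
    if spec.ice_threshold is not None:
        ice = clean < spec.ice_threshold
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    return TemperatureGrid(lats=lats, lons=lons, years=years, temps=temps, ice=ice)


def _ar1_filter(eps: np.ndarray, rho: float) -> np.ndarray:
    """Impose lag-one autocorrelation along the flattened month axis."""
    n_years, _, n_lat, n_lon = eps.shape
    flat = eps.reshape(n_years * 12, n_lat, n_lon)
    out = np.empty_like(flat)
    scale = np.sqrt(1.0 - rho * rho)
    out[0] = flat[0]
    for t in range(1, flat.shape[0]):
        out[t] = rho * out[t - 1] + scale * flat[t]
    return out.reshape(eps.shape)


def expected_gradient(spec: SyntheticSpec, centre_month: int, hemisphere: str = "north") -> float:
    """Closed-form climatological gradient (°C month⁻¹) at the start year.

    The central difference of the sinusoid: (S(m+1) − S(m−1))/2 =
    A·sin(π/6)·cos(θ_m) = 0.5·A·cos(θ_m), with θ_m the phase at the
    centre month's mid-month day.
    """
    phase_h = np.pi if hemisphere == "south" else 0.0

    def s(month: float) -> float:
        return float(
            np.sin(2.0 * np.pi * mid_month_day(month) / DAYS_PER_YEAR + BASE_PHASE + phase_h)
        )

    return spec.amplitude * (s(centre_month + 1) - s(centre_month - 1)) / 2.0


def expected_shift(spec: SyntheticSpec, centre_month: int, hemisphere: str = "north") -> float:
    """The shift (days decade⁻¹) the synthetic climate truly injects.

    A pure phase drift of δ days yr⁻¹ is by construction a shift of
    10·δ days decade⁻¹ at every centre month.  A pure warming trend b
    implies b / (0.5·A·cos θ_m) months yr⁻¹ through the finite-difference
    gradient.  Mixed cases add the two contributions, exact to first
    order in the perturbations.

    Raises
    ------
    UndefinedShiftError
        When the expected gradient is (numerically) zero.
    """
    drift_part = spec.phase_drift * 10.0
    if spec.warming_trend == 0.0:
        return drift_part
    grad = expected_gradient(spec, centre_month, hemisphere)
    if abs(grad) < 1e-9:
        raise UndefinedShiftError(
            f"expected gradient ~ 0 at centre month {centre_month}; shift undefined"
        )
    return drift_part + (spec.warming_trend / grad) * MONTH_PER_YEAR_TO_DAYS_PER_DECADE
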