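"""Shared fixtures and independent construction helpers.

The helpers here build monthly series from first principles (plain
numpy sinusoids on a 365.25-day calendar) so tests do not depend on the
package's own synthetic generator when checking the core statistic.
"""

import numpy as np
import pytest

DAYS_PER_YEAR = 365.25
DAYS_PER_DECADE_PER_MONTH_YEAR = 10 * DAYS_PER_YEAR / 12  # 304.375


def mid_month_days(months=None):
    if months is None:
        months = np.arange(1, 13)
    return (np.asarray(months, dtype=float) - 0.5) * DAYS_PER_YEAR / 12


# base phase anchoring the seasonal maximum at mid-August (northern lake)
BASE_PHASE = np.pi / 2 - 2 * np.pi * float(mid_month_days(8)) / DAYS_PER_YEAR


def month_phase(months=None):
    """Seasonal-cycle phase θ_m at mid-month, August-peak convention."""
    return 2 * np.pi * mid_month_days(months) / DAYS_PER_YEAR + BASE_PHASE


def sinusoid_matrix(n_years=42, amplitude=10.0, mean=15.0, trend=0.0, drift=0.0, phase=BASE_PHASE):
    """(n_years, 12) monthly values of a drifting, warming sinusoid."""
    dy = np.arange(n_years)[:, None]
    d = mid_month_days()[None, :]
    arg = 2 * np.pi * (d + drift * dy) / DAYS_PER_YEAR + phase
    return mean + amplitude * np.sin(arg) + trend * dy


def drift_estimator_value(delta, n_years):
    """Closed-form value the trend/gradient statistic takes on a pure
    phase drift of ``delta`` days/yr (interior centre months).

    Derived by trigonometric identities, independently of the package:
    the OLS trend of A·sin(θ + cΔ) is A·f·cos(θ + cΔ̄) with
    f = Σu·sin(cu)/Σu², and the mean central-difference gradient is
    0.5·A·D·cos(θ + cΔ̄) with D = mean(cos(cu)), u the centred year
    index and c = 2πδ/365.25; the month phase θ cancels in the ratio.
    """
    c = 2 * np.pi * delta / DAYS_PER_YEAR
    u = np.arange(n_years) - (n_years - 1) / 2
    f = np.sum(u * np.sin(c * u)) / np.sum(u * u)
    big_d = np.mean(np.cos(c * u))
    return 2 * f / big_d * DAYS_PER_DECADE_PER_MONTH_YEAR


def ols_slope_oracle(x, y):
    """Normal-equations OLS slope, the textbook Σ-based closed form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    return (n * np.sum(x * y) - np.sum(x) * np.sum(y)) / (
        n * np.sum(x * x) - np.sum(x) ** 2
    )


def quantile_oracle(values, p):
    """Sort-based quantile with linear interpolation between order stats."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * p
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


@pytest.fixture
def years42():
    return np.arange(1980, 2022)
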