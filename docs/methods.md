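# Methods

## The seasonal-shift statistic

For a location's monthly mean surface water temperature record
`T[y, m]` (year × month, °C) and a 3-month season centred on month
*m*, the package estimates

* **trend** `b_m` (°C yr⁻¹): the OLS slope of `T[·, m]` on calendar
  year, missing years dropped pairwise.  The trend uses the centre
  month only, not a 3-month pooled mean.
* **climatological seasonal gradient** `g_m` (°C month⁻¹): the mean
  over years of the central difference `(T[y, m+1] − T[y, m−1]) / 2`.
  At the year boundary the window follows the calendar: a
  December-centred window pairs November of year *y* with January of
  year *y + 1* (the final December is dropped when its following
  January is absent), and a January-centred window reaches back to the
  previous December.
* **shift** = `b_m / g_m × 304.375` days decade⁻¹ (10 years ×
  365.25 / 12 days per month).  Positive = the season's temperatures
  arrive earlier.  A zero gradient raises an error rather than
  returning an infinite shift.

The ratio interprets a monthly warming as a displacement along the
climatological seasonal cycle: if April warms by `b` and the lake
climatologically warms by `g` per month in spring, the April thermal
regime arrives `b/g` months earlier per year.

## Exclusion rules

Evaluated in a fixed order per location — ice cover, data
completeness, seasonality — so that exclusion reasons are stable and
maps can be stippled by category:

| rule | default | note |
|---|---|---|
| ice cover | ≥ 90% of years with ice in any window month | one anomalous icy year never excludes a lake |
| completeness | > 25% missing centre-month values → insufficient | also requires ≥ 3 trend points and ≥ 3 gradient year pairs |
| seasonality | \|g\| < 0.5 °C month⁻¹ → excluded | applied to the magnitude (autumn gradients are negative); exactly 0.5 is retained |

All thresholds are parameters (`ExclusionCriteria`); defaults above.
Temperatures are °C internally; Kelvin input (all finite values above
150) is converted at ingest with a log entry.

## Seasons

Fixed seasons are hemisphere-aware (latitude ≥ 0 is "north", a single
deterministic rule for the equator): northern spring = March–May
centred April, summer = June–August, autumn = September–November;
southern seasons six months later.  The moving-window variant runs all
twelve 3-month windows, wrapping the year boundary, for lakes (e.g.
very deep ones) whose thermal maximum falls outside the fixed summer.
Months are 1-based, January = 1.

## Grid pipeline

`compute_grid_shifts` vectorises the per-location statistic over
(lat, lon) grids with NaN-aware normal equations; it is cell-for-cell
identical (to ~1e-15 relative) to looping the scalar path, which the
test suite enforces against a naive loop on a 20×20 grid.  Derived
products:

* **summer lengthening** = summer shift − autumn shift where both are
  valid; an invalid input invalidates the difference and the location
  inherits the first invalid input's reason (summer checked first).
  Because the valid sets differ between seasons, the three products
  have three different `n`s and all are reported.
* **ensemble mean**: the statistic is computed per member
  (lake model × climate model) and then averaged over the members
  where the location is valid.  A location is valid in the mean when
  at least half the members are valid; invalid locations carry the
  modal reason among invalid members (ties resolved toward ice).
  Member values are summed in sorted order so the mean is bit-identical
  under member permutation.
* **summaries**: median and 25th/75th percentiles (linear
  interpolation between order statistics) over valid locations of a
  region, with `n`; medians because the per-lake shift distribution
  has long tails.  No area weighting: each grid cell's representative
  lake counts once.

## Synthetic climates

The generator produces the structure the analysis assumes: a
sinusoidal annual cycle of amplitude `A` around a mean, an optional
linear warming `b`, an optional phase drift `δ` (the whole cycle
translated `δ` days earlier per year), i.i.d. Gaussian observation
noise (optional AR(1) along the month axis, off by default), and ice
flags where the noiseless temperature falls below a freezing
threshold.  Southern-hemisphere cells carry the cycle offset six
months.  Defaults mirror a mid-latitude 42-year record starting 1980:
mean 15 °C, amplitude 10 °C — so the default spring/summer/autumn
gradients (+4.33, +2.5, −4.33 °C month⁻¹) all clear the 0.5 °C month⁻¹
criterion.

Design choices worth knowing:

* **Calendar**: a fixed 365.25-day year; monthly values are point
  evaluations at mid-month, not calendar-month integrals.  Adequate
  for a monthly-resolution statistic; it slightly understates the
  amplitude a true monthly integral would give, which cancels in the
  trend/gradient ratio.
* **Phase anchor**: the northern thermal maximum sits at mid-August —
  lake surfaces lag solar forcing — making May the steepest
  climatological rise, where the central-difference gradient is
  exactly `0.5·A`, and November the steepest fall.
* **Ice from the noiseless signal**: observation noise should not
  flicker ice cover on and off between replicates.

Closed-form ground truth (`expected_shift`): a pure drift `δ` is by
construction `10·δ` days decade⁻¹ at every month; pure warming `b`
gives `b / (0.5·A·cos θ_m) × 304.375` through the finite-difference
gradient of the sinusoid; mixed cases add the two contributions (exact
to first order).

### What recovery tests do and do not show

The estimator applied to a pure phase drift is *not* unbiased: the
central difference underestimates the true derivative of a sinusoid by
`sin(π/6)/(π/6)`, inflating the estimated shift by a factor π/6 ÷ 0.5
≈ 1.047 (+4.7%) independent of month and amplitude.  Over a finite
record the drifting climatology attenuates the gradient further
(Dirichlet-kernel factor) while curvature damps the OLS trend; at
δ = 1 day yr⁻¹ over 42 years the net bias is +5.64% at interior centre
months (+3.99% at the year-wrap months, which drop one year).  The
test suite pins the estimate to this closed form tightly rather than
pretending the bias away; the bias shrinks to the +4.7% linearization
floor as δ → 0.  Warming-trend recovery has no such bias — the same
finite-difference gradient appears in estimator and truth — and is
exact to rounding at interior months; January/December windows pick up
a small O(b/2) gradient offset from reaching into the adjacent year.

The synthetic climate is a single harmonic with stationary amplitude:
it does not emulate asymmetric seasonal cycles, amplitude trends,
skewed noise, spatially correlated forcing or partial-year ice.
Passing recovery tests therefore demonstrates correctness of the
estimator on the model it assumes, not robustness of the shift
interpretation for real lakes with evolving seasonal shapes.

## Input handling

NetCDF grids are read through xarray (classic NetCDF3 via the scipy
engine): CF-style `(time, lat, lon)` layout, time resolvable to
(year, month), sub-monthly axes averaged to calendar months with a log
notice, Kelvin declared or auto-detected, longitudes normalised to
[−180, 180), descending latitude axes flipped.  Shift maps round-trip
through NetCDF (shift/trend/gradient/valid/reason layers; reason codes
0 = none, 1 = ice_covered, 2 = insufficient_data, 3 = low_seasonality
are a stable contract) and export as per-location CSV; per-lake input
is a long-format table (`lake, year, month, temp[, ice]`).

## Problem sizes

Verification runs use 42-year records (the historic study-period
length) on grids up to 20×20 for the vectorised-vs-loop equivalence
check, 200 replicates for noisy-recovery statistics, and a 12×8
hemisphere-spanning survey grid in the acceptance script — sizes at
which every closed-form comparison is exact to the stated tolerances
and the whole suite runs in seconds.

## Known limitations

* The statistic is undefined where seasonality is weak; the 0.5
  °C month⁻¹ floor removes those lakes rather than reporting unstable
  ratios, so hemispheric medians describe only the retained set.
* Phase-drift estimates carry the intrinsic +4.7% finite-difference
  bias discussed above.
* The trend is a straight line over the whole period; accelerating
  warming is summarised, not resolved.
* Ice handling is binary per month; partial ice cover within a month
  is not represented.
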