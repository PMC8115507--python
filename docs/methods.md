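# Methods

## Scope and model chain

`pondwi` estimates the spatio-temporal availability of potential
malaria-vector larval habitats from daily gridded surface-layer soil
saturation. The chain is:

synthetic domain + forcing → daily bucket water balance (baseline and
irrigation scenarios) → ponding threshold calibration (POD) → Wetness
Index (WI) → exceedance probability maps, coverage series, stability
classes → scenario hypothesis tests.

The package does not solve subsurface or overland-flow physics
(Richards' equation, diffusive-wave routing, land-surface energy
balance are out of scope by design); the bucket model is an explicit,
mass-conserving emulator whose role is to produce saturation and
flowrate cubes with the statistical structure the habitat analysis
needs.

## Synthetic domain

`make_domain` builds a valley landscape on an `n_rows × n_cols` grid
(default 80×60 at 50 m; 332×248 is supported): a meandering
north–south channel carved to descend strictly, with elevation rising
away from it plus smoothed Gaussian noise; a riparian corridor (the
channel's 8-neighborhood); slow-draining clay-like soil (`SLOW`) on the
low flat ground and freely draining soil (`FAST`) elsewhere; and four
contiguous rectangular farm parcels centred on the slow flats, covering
approximately `farm_fraction` of the grid (default 0.25, split into
NW/NE/SW/SE quadrants numbered 1–4). D8 flow directions point to the
steepest strictly lower neighbor (ties → lowest direction code); cells
with no lower neighbor are pits, which makes the routing graph acyclic
by construction.

## Forcing

`make_forcing` draws daily rainfall from a two-regime wet-day mixture:
wet-day probability 0.65 and mean wet-day depth 11 mm in the rainy
months (May–October), 0.12 and 3.5 mm otherwise (gamma-distributed
depths, shape 0.9). A fixed seven-day storm (18–42 mm/day) is planted
on May 5–11 to provide the rainy-season onset event, and the remaining
days are rescaled so the annual sum equals the climatological target
(default 1477 mm). PET is a smooth seasonal cosine (4.5 ± 1.3 mm/day)
peaking in the dry season. The planted storm is kept at fixed depth so
that its peak drives most of the domain above ~0.85 saturation, the
qualitative signature the habitat statistics rely on.

## Irrigation schedule

Two farm groups ({1,3} then {2,4}) alternate 10-day sprinkler turns
through the dry months (Jan–Apr, Nov–Dec), 10 mm/day per farm on turn;
the 22 h/day application window is metadata only at daily resolution.
The cycle counts active-month days from January 1 (group A first), so
November resumes where April stopped; the original schedule's phase is
not documented anywhere we could follow, so group A starting the year
is a package convention.

## Bucket water balance

Each cell holds one store W (mm) for the 25 cm surface layer with
capacity = effective porosity × 250 mm: 110 mm (SLOW), 100 mm (FAST),
120 mm (RIPARIAN). Daily update order: add rainfall + irrigation +
run-on (previous-day runoff of immediate upslope neighbors, an explicit
one-cell-per-day lag that avoids within-day ordering dependence);
subtract ET = `et_coeff · PET · S` (S at start of day) and drainage
`drainage_coeff · (1 + slope_drainage_gain · slope) · W` with
per-class coefficients 0.035/0.25/0.06 day⁻¹ (SLOW/FAST/RIPARIAN) and
slope gain 5; spill storage above capacity as runoff routed along the
D8 direction; top riparian cells up to a floor saturation of 0.92
(booked as an external baseflow input). Saturation is W/capacity.

The coefficients were chosen to reproduce the documented regime rather
than point hydrology: FAST soil dries below the ponding threshold about
5 days after a storm (e-folding time 4 days), SLOW soil retains storm
water for weeks so the clay flats pond persistently through the rainy
season (year-round P(WI>10) ≈ 0.4–0.5 there, ≈ 0.2 or less on FAST
soil), and the riparian corridor never dries. Spatial heterogeneity —
±10% uniform capacity jitter and a log-uniform drainage factor in
[e⁻⁰·⁷, e⁰·⁷] — represents within-class soil variability; it spreads
cell ponding thresholds and maximum spell durations continuously, which
is what makes the survey-based threshold recovery and the
temporary/semi-permanent/permanent mix possible.

The diagnostic flowrate Q accumulates each day's runoff down the full
D8 network plus a 70% share of the day's drainage as same-day channel
baseflow, converted to m³/s by cell area; this keeps the stream
corridor above the 0.01 m³/s masking threshold year-round without a
channel-hydraulics model. Q is a flux diagnostic; only the runoff lag
and the riparian top-up move storage.

Mass balance is tracked exactly: Δstorage + in-transit runoff =
rain + irrigation + baseflow − ET − drainage − outlet outflow. The
residual closes to ~1e−16 relative and is asserted ≤ 1e−6 in tests.
Because every loss term is linear in W with coefficients < 1/day, the
daily map is monotone in storage, which yields the guarantee that an
irrigation scenario's saturation is pointwise ≥ the baseline's under
shared forcing.

## Survey generator

`make_survey` samples rainy-season points from cells whose rainy-season
maximum saturation is ≥ `theta_true`, and always includes the eligible
cell with the smallest such maximum. The strictest threshold that
detects all usable points is therefore pinned within one grid step of
`theta_true` whenever the domain ponds near it (with the default
heterogeneity it does). A configurable share of points gets habitat
types the model cannot represent (man-made ponds, tire tracks, animal
footprints); unless every point is excluded, the pinned point is kept
usable. Defaults (134 points, 32 excluded → 102 usable) mirror the
survey the analysis is designed around. Only presence-level fields are
generated: calibration uses locations as evidence of ponding, so larval
density and habitat dimensions would be dead weight.

## Threshold calibration

Detection rule: a point is detected at θ if its cell reaches S ≥ θ on
at least one day of the season window (May 1–Oct 31 by default). This
is the weakest rule consistent with a survey of observed ponds; a
persistence requirement (several consecutive days) would be a stricter
alternative and is noted as future work. POD(θ) is non-increasing and
POD(0) = 1, so maximizing POD alone is degenerate; the selected
threshold is the **largest** grid value (grid step 0.01) attaining the
maximal POD — the strictest θ that still detects everything, minimizing
overprediction, which cannot be measured directly because the survey
contains no ponding-free locations. The bootstrap protocol
(1000 with-replacement resamples, out-of-bag validation, median of
selections snapped to the grid; empty out-of-bag sets recorded as
missing) is a package convention: it is deterministic given the seed
and configurable where users have their own protocol.

## Wetness index and habitat statistics

WI uses S ≥ θ (boundary days count as ponded) and always runs from
day 1 of the simulated year; seasonal statistics window the resulting
cube rather than restarting the recurrence, so early-season WI values
carry memory of the preceding months — deliberate, since habitat
persistence does not reset on a calendar boundary.

`P(WI>T)` and `F(WI>T)` both use the strict comparator `>` by default;
a `geq` switch is provided for the coverage definition because the two
printed definitions of "exceeding" are not mutually consistent in the
source material and users may want either. The dry period pools its two
month blocks (Jan–Apr, Nov–Dec) into one day set without reweighting.
Stability classes are left-closed/right-open ([15,90), [90,180),
[180,∞) days); the histogram uses 15-day bins with a final open bin at
360+. The stream mask (Q > 0.01 m³/s on ≥ 90% of days) is applied to
all per-cell statistics by default (`apply_mask_to_stats`), and the
baseline scenario's mask is used for both scenarios so comparisons run
over identical cell sets.

## Scenario tests

Wilcoxon rank-sum (one-sided, irrigation stochastically greater) on
per-cell P values: exact enumeration for tie-free samples with
n ≤ 20, tie-corrected normal approximation otherwise; two identical
constant samples report p = 0.5 with a degenerate flag. Monthly
coverage uses a one-sided Welch (unequal-variance) t-test on the
month's daily F values, flagged at 0.01. Per-cell values are treated as
independent observations; spatial autocorrelation inflates the
effective sample size and is deliberately not corrected, to keep the
procedure faithful to common practice in this literature — p-values
should be read as descriptive, not strictly calibrated, when cells are
strongly correlated. No multiple-testing correction is applied.

## Numerical and testing notes

- Problem sizes: tests use 24×20 to 80×60 grids over one 365-day year;
  50×50×365 cubes for the oracle checks; 20 replicates × 3 planted
  thresholds with 200 bootstrap resamples for calibration recovery;
  1000 null simulations (n = 50 per sample) for empirical test size.
  These sizes make the full suite run in well under a minute while
  leaving every check statistically meaningful.
- Determinism: one root seed is expanded per stage via CRC-tagged
  `SeedSequence`s; repeated runs are byte-identical including NetCDF
  artifacts (classic-format NetCDF-3 via xarray's scipy engine, int32
  CF times, no timestamps).
- Degenerate inputs are first-class: NaN forcing or saturation errors
  name the offending date/cell; empty regions, empty windows,
  unpondable domains and fully filtered surveys raise informative
  errors rather than propagating empties.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the study system — seasonal
rainfall with a planted onset storm, contrasting drainage classes,
persistently wet stream corridors, rotating dry-season irrigation, a
rainy-season ponding survey — and the analysis reproduces the
qualitative findings end-to-end (dry-season habitat creation inside
farms, no effect outside, semi-permanent → permanent stability shift,
rainy-season peak coverage ~0.8 inside farms). It does not emulate
spatially correlated rainfall, hourly dynamics, groundwater-fed
ponding, real terrain, or survey placement bias; passing tests
therefore validate the statistical machinery and its contracts, not
hydrological skill on any real landscape.
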