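# pondwi

Ponding-persistence mapping of potential malaria-vector larval habitats
under rainfall and irrigation.

Malaria larval source management needs to know *where* water ponds, *how
long* it persists, and *how irrigation changes both*. `pondwi` answers
those questions on a gridded study domain (an irrigated river-valley
plantation at 50 m resolution) by turning daily surface-layer soil
saturation into habitat statistics:

- **Wetness Index.** For each cell (x, y) and day t,

  `WI(x,y,t) = WI(x,y,t-1) + 1` if `S(x,y,t) >= θ`, else `0`,

  i.e. the number of consecutive days a cell has been ponded, where
  `S ∈ [0,1]` is the saturation of the 25 cm surface soil layer and `θ`
  is a calibrated ponding threshold. A spell must outlast the aquatic
  development time of *Anopheles* larvae — T = 10 days (critical) or
  15 days (normal) — for the cell to count as a potential habitat.
- **Threshold calibration.** θ is fitted against a survey of observed
  ponding locations by maximizing the probability of detection (POD):
  the selected θ is the largest grid value that still detects every
  usable point, with bootstrap resampling (out-of-bag validation, median
  aggregation) for robustness. Habitat types a gridded soil-moisture
  model cannot represent (man-made ponds, tire tracks, animal
  footprints) and dry-season points are excluded first.
- **Habitat statistics.** Per-cell exceedance probability
  `P(WI>T) = D(WI>T) / D_period` over the year, dry season (Nov–Apr) and
  rainy season (May–Oct); daily fractional coverage
  `F(WI>T) = C(WI>T) / C_region` over the farm area with monthly means
  and 95% CIs; stability classes from each cell's longest ponding spell
  (non-habitat < 15 d, temporary 15–90 d, semi-permanent 90–180 d,
  permanent ≥ 180 d); a mask for persistently fast-flowing stream cells
  (Q > 0.01 m³/s on ≥ 90% of days) where larvae cannot hold.
- **Scenario comparison.** Baseline vs rotating dry-season sprinkler
  irrigation (four farm parcels, two groups alternating 10-day turns at
  10 mm/day), compared by one-sided Wilcoxon rank-sum tests on per-cell
  P(WI>T) and one-sided Welch t-tests on monthly coverage.

Because the original forcing, terrain and survey data are not publicly
deposited, the package ships a first-class synthetic hydrology module: a
mass-conserving daily bucket model with D8 routing over a generated
valley domain (slow-draining vertisol flats, fast-draining slopes, a wet
riparian corridor, four farm parcels) plus seasonal rainfall forcing and
synthetic survey points with a planted recoverable threshold. Every
downstream statistic is exercised end-to-end without downloads.

## Worked example

```sh
python examples/03_habitat_maps.py
```

prints, for the default seed:

```
stream mask removes 67 fast-flowing cells (1.4% of the domain)
  baseline  YEAR: median P(WI>10) inside farms = 0.449
  baseline   DRY: median P(WI>10) inside farms = 0.000
  baseline RAINY: median P(WI>10) inside farms = 0.891
irrigation  YEAR: median P(WI>10) inside farms = 0.510
irrigation   DRY: median P(WI>10) inside farms = 0.077
irrigation RAINY: median P(WI>10) inside farms = 0.908

stability of farm cells (fraction of farm area):
  baseline: non_habitat 21.2%, temporary 6.9%, semi_permanent 42.1%, permanent 29.8%
irrigation: non_habitat 21.2%, temporary 6.9%, semi_permanent 25.7%, permanent 46.2%
```

Reading: without irrigation, half the farm area is a potential larval
habitat on ~45% of the year's days, almost entirely during the rainy
season. Dry-season irrigation lifts the dry-season median from 0 to
~0.08 (many cells pond through the irrigation turns) and converts
semi-permanent habitats into permanent ones — the farm becomes a
year-round mosquito breeding ground. The other examples simulate the
scenarios (`01`), calibrate θ (`02`, recovering θ* = 0.48 with POD 1.0)
and run the hypothesis tests (`04`).

A thin CLI wraps the same library:

```sh
pondwi run-all --seed 1 --out out/        # full pipeline + manifest
pondwi simulate | calibrate | wi | metrics | compare | make-fixtures
```

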