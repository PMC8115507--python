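"""Habitat statistics from wetness-index cubes.

Covers the stream mask (fast-flowing cells are poor larval habitat),
per-cell exceedance probability maps P(WI > T), daily fractional coverage
series F(WI > T) over a region, monthly mean coverage with normal 95%
confidence intervals, and stability classification of cells by their
maximum ponding duration (non-habitat / temporary / semi-permanent /
permanent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cubes import FlowCube, WetnessCube

__all__ = [
    "SeasonDefinition", "ExceedanceMap", "CoverageSeries", "StabilityMap",
    "stream_mask", "exceedance_probability", "coverage_series",
    "monthly_mean_coverage", "classify_stability",
    "STABILITY_CLASSES",
]

PERIODS = ("YEAR", "DRY", "RAINY")

# Stability class codes and the left-closed/right-open day boundaries.
STABILITY_CLASSES = {0: "NON_HABITAT", 1: "TEMPORARY",
                     2: "SEMI_PERMANENT", 3: "PERMANENT"}
_CLASS_EDGES = (15, 90, 180)  # <15 | [15,90) | [90,180) | >=180


@dataclass(frozen=True)
class SeasonDefinition:
    """Dry/rainy month partition of the year (defaults: Nov-Apr / May-Oct)."""

    dry_months: frozenset = frozenset({1, 2, 3, 4, 11, 12})
    rainy_months: frozenset = frozenset({5, 6, 7, 8, 9, 10})

    def __post_init__(self) -> None:
        if set(self.dry_months) | set(self.rainy_months) != set(range(1, 13)):
            raise ValueError("dry and rainy months must cover all 12 months")
        if set(self.dry_months) & set(self.rainy_months):
            raise ValueError("dry and rainy months must be disjoint")

    def months_for(self, period: str) -> frozenset:
        period = period.upper()
        if period == "YEAR":
            return frozenset(range(1, 13))
        if period == "DRY":
            return self.dry_months
        if period == "RAINY":
            return self.rainy_months
        raise ValueError(f"unknown period {period!r}")


@dataclass
class ExceedanceMap:
    """Per-cell P(WI > T) for one period and scenario; NaN where masked."""

    values: np.ndarray
    T: int
    period: str
    scenario_label: str = ""
    mask_applied: bool = False

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("exceedance probabilities must lie in [0, 1]")


@dataclass
class CoverageSeries:
    """Daily F(WI > T): ponded-beyond-T fraction of a region's cells."""

    values: np.ndarray
    dates: pd.DatetimeIndex
    T: int
    region: str = "CUSTOM"

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.dates),):
            raise ValueError("series length must match the calendar")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("coverage fractions must lie in [0, 1]")


@dataclass
class StabilityMap:
    """Per-cell stability class with a 15-day max-duration histogram."""

    classes: np.ndarray          # uint8 codes per STABILITY_CLASSES, 255 masked
    max_duration: np.ndarray     # days
    histogram: pd.DataFrame      # bin_start, bin_end, count, fraction
    fractions: dict = field(default_factory=dict)  # class name -> area fraction


def stream_mask(flow: FlowCube, q_threshold: float = 0.01,
                persistence: float = 0.9) -> np.ndarray:
    """Cells whose flowrate exceeds *q_threshold* m^3/s most of the time.

    A cell is masked (True) when Q > q_threshold on at least a
    ``persistence`` fraction of the days — fast-moving water where larvae
    are unlikely to survive.
    """
    frac = np.mean(flow.values > q_threshold, axis=0)
    return frac >= persistence


def exceedance_probability(wi: WetnessCube, T: int, period: str = "YEAR",
                           seasons: SeasonDefinition | None = None,
                           mask: np.ndarray | None = None) -> ExceedanceMap:
    """P(WI > T): the fraction of the period's days a cell's WI exceeds T.

    The dry period pools its two non-contiguous month blocks into one day
    set.  Masked cells are set to NaN (missing), never zero.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    seasons = seasons or SeasonDefinition()
    months = seasons.months_for(period)
    day_sel = np.isin(wi.dates.month, list(months))
    n_days = int(day_sel.sum())
    if n_days == 0:
        raise ValueError(f"period {period} has no days in the calendar")
    p = (wi.values[day_sel] > T).sum(axis=0) / n_days
    p = p.astype(float)
    if mask is not None:
        p[mask] = np.nan
    return ExceedanceMap(values=p, T=int(T), period=period.upper(),
                         scenario_label="", mask_applied=mask is not None)


def coverage_series(wi: WetnessCube, T: int, region_cells: np.ndarray,
                    comparator: str = "strict",
                    region: str = "CUSTOM") -> CoverageSeries:
    """Daily fractional coverage F(WI > T) over a cell region.

    ``region_cells`` is a boolean map over the grid.  ``comparator``
    selects strict ``WI > T`` (default) or ``WI >= T`` ("geq").
    """
    region_cells = np.asarray(region_cells, dtype=bool)
    if region_cells.shape != wi.shape[1:]:
        raise ValueError("region mask shape must match the grid")
    n_region = int(region_cells.sum())
    if n_region == 0:
        raise ValueError("region is empty")
    vals = wi.values[:, region_cells]
    if comparator == "strict":
        count = (vals > T).sum(axis=1)
    elif comparator == "geq":
        count = (vals >= T).sum(axis=1)
    else:
        raise ValueError("comparator must be 'strict' or 'geq'")
    return CoverageSeries(values=count / n_region, dates=wi.dates,
                          T=int(T), region=region)


def monthly_mean_coverage(series: CoverageSeries) -> pd.DataFrame:
    """Monthly mean coverage with normal-approximation 95% CIs.

    Returns one row per calendar month present in the series with columns
    ``month, mean, ci95_low, ci95_high, n_days, complete``; months only
    partially covered by the calendar are flagged ``complete=False``.
    """
    df = pd.DataFrame({"date": series.dates, "F": series.values})
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    rows = []
    for (year, month), grp in df.groupby(["year", "month"], sort=True):
        n = len(grp)
        full = pd.Period(f"{year}-{month:02d}").days_in_month
        mean = grp["F"].mean()
        sd = grp["F"].std(ddof=1) if n > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n) if n > 1 else 0.0
        rows.append({"year": year, "month": month, "mean": mean,
                     "ci95_low": mean - half, "ci95_high": mean + half,
                     "n_days": n, "complete": n == full})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("series covers no full month")
    return out


def classify_stability(max_duration: np.ndarray,
                       mask: np.ndarray | None = None) -> StabilityMap:
    """Classify cells by maximum ponding duration.

    Non-habitat < 15 days, temporary [15, 90), semi-permanent [90, 180),
    permanent >= 180 days; the histogram uses 15-day bins with a final
    open bin for 360 days and above.  Fractions are taken over unmasked
    cells.
    """
    max_duration = np.asarray(max_duration)
    if (max_duration < 0).any():
        raise ValueError("max ponding durations must be non-negative")
    classes = np.zeros(max_duration.shape, dtype=np.uint8)
    classes[max_duration >= _CLASS_EDGES[0]] = 1
    classes[max_duration >= _CLASS_EDGES[1]] = 2
    classes[max_duration >= _CLASS_EDGES[2]] = 3

    valid = np.ones(max_duration.shape, dtype=bool) if mask is None else ~mask
    classes_out = classes.copy()
    classes_out[~valid] = 255
    durations = max_duration[valid]
    n_valid = durations.size
    if n_valid == 0:
        raise ValueError("no unmasked cells to classify")

    edges = list(range(0, 375, 15))  # [0,15), ..., [345,360), then 360+
    counts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        counts.append(int(((durations >= lo) & (durations < hi)).sum()))
    counts.append(int((durations >= 360).sum()))
    starts = edges[:-1] + [360]
    ends = edges[1:] + [np.inf]
    hist = pd.DataFrame({"bin_start": starts, "bin_end": ends,
                         "count": counts,
                         "fraction": np.array(counts) / n_valid})

    fractions = {name: float((classes[valid] == code).sum() / n_valid)
                 for code, name in STABILITY_CLASSES.items()}
    return StabilityMap(classes=classes_out, max_duration=max_duration,
                        histogram=hist, fractions=fractions)
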