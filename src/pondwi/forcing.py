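"""Synthetic daily meteorological forcing and rotating sprinkler irrigation.

Rainfall follows a seasonal wet-day mixture (wetter and heavier May-October)
scaled to a configurable annual total, with a multi-day storm planted in
early May to reproduce the onset-of-rainy-season event used for
illustration.  Irrigation rotates two groups of farm parcels on a fixed
turn length through the dry months.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ForcingSeries", "IrrigationSchedule", "make_forcing",
           "irrigation_depth", "irrigation_calendar"]

RAINY_MONTHS_DEFAULT = frozenset({5, 6, 7, 8, 9, 10})
DRY_MONTHS_DEFAULT = frozenset({1, 2, 3, 4, 11, 12})


@dataclass
class ForcingSeries:
    """One year of daily rainfall and potential evapotranspiration (mm/day)."""

    dates: pd.DatetimeIndex
    rainfall: np.ndarray  # (n,) mm/day
    pet: np.ndarray       # (n,) mm/day

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.rainfall = np.asarray(self.rainfall, dtype=float)
        self.pet = np.asarray(self.pet, dtype=float)
        n = len(self.dates)
        if self.rainfall.shape != (n,) or self.pet.shape != (n,):
            raise ValueError("rainfall and pet must match the calendar length")
        with np.errstate(invalid="ignore"):
            if np.any(self.rainfall < 0) or np.any(self.pet < 0):
                raise ValueError("rainfall and pet must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass(frozen=True)
class IrrigationSchedule:
    """Rotating two-group sprinkler schedule over the dry months.

    Farms in ``group_a`` are irrigated for ``turn_length`` days, then farms
    in ``group_b``, alternating through the months in ``active_months``.
    Each farm on turn receives ``daily_depth`` mm/day, delivered over
    ``hours_per_day`` hours (metadata only at daily resolution).
    """

    group_a: frozenset = frozenset({1, 3})
    group_b: frozenset = frozenset({2, 4})
    turn_length: int = 10
    daily_depth: float = 10.0  # mm/day
    hours_per_day: float = 22.0
    active_months: frozenset = frozenset({1, 2, 3, 4, 11, 12})
    enabled: bool = True

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("irrigation groups must be disjoint")
        if self.turn_length < 1:
            raise ValueError("turn_length must be >= 1")
        if self.daily_depth < 0:
            raise ValueError("daily_depth must be >= 0")


def make_forcing(dates: pd.DatetimeIndex, seed: int,
                 rainy_months: frozenset = RAINY_MONTHS_DEFAULT,
                 annual_total: float = 1477.0) -> ForcingSeries:
    """Generate a year of daily rainfall and PET.

    Wet-day probability and mean wet-day depth are higher in
    ``rainy_months``; the whole series is rescaled so the annual sum equals
    ``annual_total`` (default 1477 mm, the study area's climatology).  A
    seven-day storm is planted on May 5-11 (when May is a rainy month and
    covered by the calendar), emulating the peak onset event.  PET is a
    smooth seasonal curve peaking in the dry season.
    """
    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValueError("forcing calendar is empty")
    rng = np.random.default_rng(seed)
    months = dates.month.values
    rainy = np.isin(months, list(rainy_months)) if rainy_months else \
        np.zeros(len(dates), dtype=bool)

    p_wet = np.where(rainy, 0.65, 0.12)
    mean_depth = np.where(rainy, 11.0, 3.5)
    wet = rng.random(len(dates)) < p_wet
    shape = 0.9
    depths = rng.gamma(shape, mean_depth / shape)
    rain = np.where(wet, depths, 0.0)

    # Plant the early-rainy-season storm at fixed depths (May 5-11) and
    # rescale the remaining days so the annual sum hits the target.
    storm_sel = np.zeros(len(dates), dtype=bool)
    if 5 in rainy_months:
        storm = {5: 18.0, 6: 30.0, 7: 42.0, 8: 38.0, 9: 26.0, 10: 16.0, 11: 10.0}
        for day, depth in storm.items():
            sel = (months == 5) & (dates.day.values == day)
            rain[sel] = depth
            storm_sel |= sel
    if annual_total > 0:
        rest = rain[~storm_sel].sum()
        budget = max(annual_total - rain[storm_sel].sum(), 0.0)
        if rest > 0:
            rain[~storm_sel] *= budget / rest

    doy = dates.dayofyear.values
    pet = 4.5 + 1.3 * np.cos(2.0 * np.pi * (doy - 20) / 365.25)
    return ForcingSeries(dates=dates, rainfall=rain, pet=pet)


def _active_day_index(schedule: IrrigationSchedule, date: _dt.date) -> int:
    """0-based count of active-month days from Jan 1 up to *date* (inclusive)."""
    start = _dt.date(date.year, 1, 1)
    days = pd.date_range(start, date, freq="D")
    active = np.isin(days.month, list(schedule.active_months))
    return int(active.sum()) - 1


def irrigation_depth(schedule: IrrigationSchedule, farm_id: int,
                     date: _dt.date | pd.Timestamp) -> float:
    """Irrigation applied to *farm_id* on *date*, in mm/day.

    The 10-day turn alternates between ``group_a`` (first) and ``group_b``,
    counting from the first active-month day of the calendar year; days in
    inactive months do not advance the cycle.  Cells outside farms
    (farm_id 0) are never irrigated.
    """
    if farm_id == 0 or not schedule.enabled:
        return 0.0
    if farm_id not in set(schedule.group_a) | set(schedule.group_b):
        raise ValueError(f"unknown farm id {farm_id}")
    date = pd.Timestamp(date)
    if date.month not in schedule.active_months:
        return 0.0
    idx = _active_day_index(schedule, date.date())
    on_a = (idx // schedule.turn_length) % 2 == 0
    group = schedule.group_a if on_a else schedule.group_b
    return schedule.daily_depth if farm_id in group else 0.0


def irrigation_calendar(schedule: IrrigationSchedule,
                        dates: pd.DatetimeIndex) -> dict[int, np.ndarray]:
    """Vectorized per-farm daily irrigation depth over *dates* (mm/day)."""
    dates = pd.DatetimeIndex(dates)
    farms = sorted(set(schedule.group_a) | set(schedule.group_b))
    out = {f: np.zeros(len(dates)) for f in farms}
    if not schedule.enabled or len(dates) == 0:
        return out
    # Cycle index counted per calendar year over active-month days.
    active = np.isin(dates.month, list(schedule.active_months))
    idx = np.full(len(dates), -1, dtype=int)
    for year in np.unique(dates.year):
        # Count from Jan 1 of the year even if the calendar starts later.
        year_start = pd.Timestamp(year=int(year), month=1, day=1)
        in_year = dates.year == year
        offsets = (dates[in_year] - year_start).days.values
        full = pd.date_range(year_start, periods=int(offsets.max()) + 1, freq="D")
        act_full = np.isin(full.month, list(schedule.active_months))
        cum = np.cumsum(act_full) - 1
        idx[in_year] = cum[offsets]
    on_a = (idx // schedule.turn_length) % 2 == 0
    for f in farms:
        in_group_a = f in schedule.group_a
        on = active & np.where(in_group_a, on_a, ~on_a)
        out[f][on] = schedule.daily_depth
    return out
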