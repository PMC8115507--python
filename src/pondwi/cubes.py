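"""Gridded daily cubes: soil saturation, surface flowrate, wetness index.

All cubes share the layout ``(time, row, col)`` with row 0 the northernmost
row and 0-based cell indices.  The time axis is a strictly increasing,
gap-free daily calendar (:class:`pandas.DatetimeIndex`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SaturationCube", "FlowCube", "WetnessCube", "check_daily_calendar"]


def check_daily_calendar(dates: pd.DatetimeIndex, n: int) -> pd.DatetimeIndex:
    """Validate a strictly increasing, gap-free daily calendar of length *n*."""
    dates = pd.DatetimeIndex(dates)
    if len(dates) != n:
        raise ValueError(f"calendar length {len(dates)} != time dimension {n}")
    if len(dates) > 1:
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if not np.all(deltas == 1):
            raise ValueError("time axis must be daily and gap-free")
    return dates


@dataclass
class SaturationCube:
    """Daily surface-layer soil saturation S(x, y, t) in [0, 1].

    Saturation of the topmost soil layer (25 cm in the default setup) is the
    quantity thresholded for ponding: a cell is deemed ponded on a day when
    S >= theta for the calibrated threshold theta.
    """

    values: np.ndarray  # (time, row, col), fraction
    dates: pd.DatetimeIndex
    scenario_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("saturation values must be (time, row, col)")
        self.dates = check_daily_calendar(self.dates, self.values.shape[0])
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("saturation must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class FlowCube:
    """Daily surface water flowrate Q(x, y, t) in m^3/s, Q >= 0."""

    values: np.ndarray  # (time, row, col), m3/s
    dates: pd.DatetimeIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("flow values must be (time, row, col)")
        self.dates = check_daily_calendar(self.dates, self.values.shape[0])
        if np.nanmin(self.values) < -1e-12:
            raise ValueError("flowrate must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class WetnessCube:
    """Wetness Index WI(x, y, t): consecutive ponded days, reset on dry days.

    WI follows the recurrence WI(t) = WI(t-1) + 1 when S(t) >= theta and 0
    otherwise, starting from WI = 0 before the first day; values are
    non-negative integers bounded by the elapsed day count.
    """

    values: np.ndarray  # (time, row, col), int days
    dates: pd.DatetimeIndex
    theta: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("wetness index must be integer days")
        if self.values.ndim != 3:
            raise ValueError("wetness values must be (time, row, col)")
        self.dates = check_daily_calendar(self.dates, self.values.shape[0])
        if self.values.min() < 0:
            raise ValueError("wetness index must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape
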