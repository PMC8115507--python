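"""Wetness Index: consecutive-day ponding persistence per grid cell.

WI(x, y, t) = WI(x, y, t-1) + 1 when S(x, y, t) >= theta, else 0, with
WI = 0 before the first simulated day.  The index is always computed over
the full simulated year from day one; seasonal analyses window the
resulting cube rather than restarting the recurrence at season boundaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cubes import SaturationCube, WetnessCube

__all__ = ["compute_wi", "max_ponding_duration"]


def compute_wi(sat: SaturationCube, theta: float) -> WetnessCube:
    """Run the ponding-persistence recurrence at threshold *theta*.

    The ponding condition is ``S >= theta`` (days exactly at the threshold
    count as ponded).
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must be in [0, 1]")
    values = sat.values
    nan = ~np.isfinite(values)
    if nan.any():
        t, r, c = np.unravel_index(int(np.argmax(nan)), values.shape)
        raise ValueError(
            f"NaN saturation at cell ({r}, {c}) on {sat.dates[t].date()}")
    n_days = values.shape[0]
    wi = np.zeros(values.shape, dtype=np.int32)
    run = np.zeros(values.shape[1:], dtype=np.int32)
    ponded = values >= theta
    for t in range(n_days):
        run = (run + 1) * ponded[t]
        wi[t] = run
    return WetnessCube(values=wi, dates=sat.dates, theta=float(theta))


def max_ponding_duration(wi: WetnessCube, window=None) -> np.ndarray:
    """Per-cell maximum WI over a date window (default: the whole cube).

    Because WI counts consecutive ponded days, the maximum over a window
    is the longest ponding spell observed up to and within it.
    """
    if window is None:
        mask = np.ones(len(wi.dates), dtype=bool)
    else:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        mask = np.asarray((wi.dates >= start) & (wi.dates <= end))
        if not mask.any():
            raise ValueError("window contains no days of the cube")
    return wi.values[mask].max(axis=0)
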