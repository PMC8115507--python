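"""Soil-saturation threshold calibration by probability of detection.

A survey point is *detected* at threshold theta when its grid cell reaches
saturation >= theta on at least one day of the season window.  The
probability of detection (POD) is the detected fraction of points; it is
non-increasing in theta and equals 1 at theta = 0, so the calibrated
threshold theta* is the **largest** grid value that still attains the
maximal POD — the strictest threshold that detects every usable point,
minimizing overprediction.  Robustness is assessed by bootstrap:
with-replacement resamples act as calibration sets, out-of-bag points as
validation sets, and theta* is the median of the per-resample selections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cubes import SaturationCube
from .survey import EXCLUDED_HABITATS

__all__ = ["CalibrationResult", "filter_survey", "pod", "calibrate_theta"]


@dataclass
class CalibrationResult:
    """Outcome of the bootstrap threshold calibration."""

    theta_star: float
    pod_curve: dict                      # {theta: POD on full usable survey}
    bootstrap_thetas: np.ndarray         # per-resample selected theta
    pod_calibration: float               # POD at theta_star, full survey
    pod_validation: float                # mean out-of-bag POD at selections
    n_points_used: int
    settings: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        grid = sorted(self.pod_curve)
        payload = {
            "theta_star": self.theta_star,
            "pod_calibration": self.pod_calibration,
            "pod_validation": self.pod_validation,
            "n_points_used": self.n_points_used,
            "settings": self.settings,
            "pod_curve": {"theta": [round(t, 6) for t in grid],
                          "pod": [self.pod_curve[t] for t in grid]},
            "bootstrap_thetas": [float(t) for t in self.bootstrap_thetas],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def filter_survey(survey: pd.DataFrame) -> pd.DataFrame:
    """Drop habitat types the model cannot represent and non-rainy rows.

    Man-made ponds, tire-track puddles and animal footprints are removed,
    as are points observed outside the rainy season (dry-season irrigation
    is only schematically represented, so dry points would bias theta).
    """
    keep = (~survey["habitat_type"].isin(EXCLUDED_HABITATS)
            & (survey["season"] == "RAINY"))
    out = survey.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("no usable survey points after filtering")
    return out


def _window_mask(dates: pd.DatetimeIndex, window) -> np.ndarray:
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    mask = (dates >= start) & (dates <= end)
    if not mask.any():
        raise ValueError("season window contains no days of the cube")
    return np.asarray(mask)


def point_max_saturation(sat: SaturationCube, points: pd.DataFrame,
                         window) -> np.ndarray:
    """Per-point maximum saturation of the containing cell over *window*."""
    n_rows, n_cols = sat.shape[1:]
    rows = points["row"].to_numpy(int)
    cols = points["col"].to_numpy(int)
    bad = (rows < 0) | (rows >= n_rows) | (cols < 0) | (cols >= n_cols)
    if bad.any():
        pid = points["point_id"].iloc[int(np.argmax(bad))]
        raise ValueError(f"survey point {pid} lies outside the grid")
    mask = _window_mask(sat.dates, window)
    return sat.values[mask][:, rows, cols].max(axis=0)


def pod(sat: SaturationCube, points: pd.DataFrame, theta: float,
        season_window) -> float:
    """Probability of detection at threshold *theta* over a date window."""
    if points.empty:
        raise ValueError("survey is empty")
    max_s = point_max_saturation(sat, points, season_window)
    return float(np.mean(max_s >= theta))


def default_rainy_window(dates: pd.DatetimeIndex) -> tuple:
    """May 1 - Oct 31 of the cube's (first) year."""
    year = int(dates[0].year)
    return (pd.Timestamp(year=year, month=5, day=1),
            pd.Timestamp(year=year, month=10, day=31))


def calibrate_theta(sat: SaturationCube, survey: pd.DataFrame,
                    theta_grid_step: float = 0.01,
                    n_bootstrap: int = 1000, seed: int = 0,
                    season_window=None) -> CalibrationResult:
    """Bootstrap-calibrate the ponding threshold against survey points.

    ``survey`` must already be passed through :func:`filter_survey`.  For
    each resample the selected threshold is the largest grid value
    attaining the maximal calibration POD; ``theta_star`` is the median of
    those selections snapped back to the grid.  Out-of-bag PODs at the
    per-resample selections are averaged into ``pod_validation`` (empty
    out-of-bag sets are recorded as missing, not zero).
    """
    if survey.empty:
        raise ValueError("survey is empty")
    if not (0.0 < theta_grid_step <= 0.5):
        raise ValueError("theta_grid_step must be in (0, 0.5]")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if season_window is None:
        season_window = default_rainy_window(sat.dates)

    grid = np.round(np.arange(0.0, 1.0 + theta_grid_step / 2.0,
                              theta_grid_step), 10)
    max_s = point_max_saturation(sat, survey, season_window)
    n = len(max_s)

    # POD(theta) on the full usable survey.
    detect = max_s[None, :] >= grid[:, None]       # (grid, points)
    full_pod = detect.mean(axis=1)
    pod_curve = {float(t): float(p) for t, p in zip(grid, full_pod)}

    rng = np.random.default_rng(seed)
    thetas = np.empty(n_bootstrap)
    oob_pods = np.full(n_bootstrap, np.nan)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        cal_pod = detect[:, idx].mean(axis=1)
        best = np.flatnonzero(cal_pod == cal_pod.max())
        theta_b = grid[best[-1]]                   # largest theta at max POD
        thetas[b] = theta_b
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size:
            oob_pods[b] = np.mean(max_s[oob] >= theta_b)

    theta_star = float(grid[np.argmin(np.abs(grid - np.median(thetas)))])
    return CalibrationResult(
        theta_star=theta_star,
        pod_curve=pod_curve,
        bootstrap_thetas=thetas,
        pod_calibration=float(np.mean(max_s >= theta_star)),
        pod_validation=float(np.nanmean(oob_pods)) if np.isfinite(
            oob_pods).any() else float("nan"),
        n_points_used=n,
        settings={
            "theta_grid_step": theta_grid_step,
            "n_bootstrap": n_bootstrap,
            "seed": seed,
            "season_window": [str(pd.Timestamp(season_window[0]).date()),
                              str(pd.Timestamp(season_window[1]).date())],
        },
    )
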