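"""Synthetic ponding survey points for threshold calibration.

The field protocol they emulate records locations where ponding was
observed (each point is evidence of ponding regardless of larval
detection), with a habitat type; some types (man-made ponds, tire tracks,
animal footprints) cannot be represented by a gridded soil-moisture model
and are excluded before calibration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cubes import SaturationCube
from .domain import DomainGrid
from .forcing import RAINY_MONTHS_DEFAULT

__all__ = ["make_survey", "SIMULATABLE_HABITATS", "EXCLUDED_HABITATS",
           "SURVEY_COLUMNS"]

SIMULATABLE_HABITATS = (
    "rain_pool", "stream_shoreline", "irrigation_canal",
    "hippo_trench", "drainage_ditch", "rice_puddle",
)
EXCLUDED_HABITATS = ("man_made_pond", "tire_track", "animal_footprint")

SURVEY_COLUMNS = ["point_id", "row", "col", "season", "habitat_type",
                  "larvae_present"]


def rainy_max_saturation(sat: SaturationCube,
                         rainy_months=RAINY_MONTHS_DEFAULT) -> np.ndarray:
    """Per-cell maximum saturation over the rainy-season days."""
    in_season = np.isin(sat.dates.month, list(rainy_months))
    if not in_season.any():
        raise ValueError("saturation cube covers no rainy-season days")
    return sat.values[in_season].max(axis=0)


def make_survey(sat: SaturationCube, domain: DomainGrid, theta_true: float,
                n_points: int, seed: int,
                frac_excluded_types: float = 0.0,
                theta_grid_step: float = 0.01) -> pd.DataFrame:
    """Sample rainy-season survey points at cells that pond at *theta_true*.

    Every point falls in a cell whose rainy-season maximum saturation is at
    least ``theta_true``.  One point is planted at the eligible cell with
    the smallest such maximum, so the strictest threshold that still
    detects all points sits within one ``theta_grid_step`` of
    ``theta_true`` whenever the domain ponds near it.  A share
    ``frac_excluded_types`` of points receives habitat types the gridded
    model cannot represent (and that calibration later removes).
    """
    if not (0.0 < theta_true < 1.0):
        raise ValueError("theta_true must be in (0, 1)")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not (0.0 <= frac_excluded_types <= 1.0):
        raise ValueError("frac_excluded_types must be in [0, 1]")

    max_s = rainy_max_saturation(sat)
    eligible = np.flatnonzero(max_s.ravel() >= theta_true)
    if eligible.size == 0:
        raise ValueError(
            f"unpondable domain: no cell reaches saturation {theta_true} "
            "in the rainy season")

    rng = np.random.default_rng(seed)
    # Planted point: the eligible cell with the smallest rainy-season max,
    # which pins the recoverable threshold at (or just above) theta_true.
    order = np.argsort(max_s.ravel()[eligible], kind="stable")
    planted = eligible[order[0]]
    rest_pool = eligible[eligible != planted]
    n_rest = n_points - 1
    if n_rest > 0 and rest_pool.size:
        replace = rest_pool.size < n_rest
        rest = rng.choice(rest_pool, size=n_rest, replace=replace)
    else:
        rest = np.full(n_rest, planted)
    cells = np.concatenate([[planted], rest])

    n_excl = int(round(frac_excluded_types * n_points))
    habitat = np.array(
        list(rng.choice(SIMULATABLE_HABITATS, size=n_points)), dtype=object)
    if n_excl > 0:
        # Keep the planted point usable unless every point is excluded.
        excl_slots = np.arange(n_points) if n_excl >= n_points else \
            1 + rng.choice(n_points - 1, size=n_excl, replace=False)
        habitat[excl_slots] = rng.choice(EXCLUDED_HABITATS,
                                         size=len(excl_slots))

    rows, cols = np.unravel_index(cells, domain.shape)
    return pd.DataFrame({
        "point_id": [f"pt{i:04d}" for i in range(n_points)],
        "row": rows.astype(int),
        "col": cols.astype(int),
        "season": "RAINY",
        "habitat_type": habitat,
        "larvae_present": rng.random(n_points) < 0.6,
    })[SURVEY_COLUMNS]
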