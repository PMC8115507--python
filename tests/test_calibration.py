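import numpy as np
import pandas as pd
import pytest

from pondwi.calibration import calibrate_theta, filter_survey, pod
from pondwi.cubes import SaturationCube
from pondwi.survey import make_survey

from conftest import YEAR_DATES

RAINY_WINDOW = (pd.Timestamp("2018-05-01"), pd.Timestamp("2018-10-31"))


def survey_frame(rows, cols, habitat="rain_pool", season="RAINY"):
    n = len(rows)
    return pd.DataFrame({
        "point_id": [f"p{i}" for i in range(n)],
        "row": rows, "col": cols,
        "season": season, "habitat_type": habitat,
        "larvae_present": True,
    })


def test_filter_keeps_only_simulatable_rainy_rows():
    df = survey_frame([0] * 6, list(range(6)))
    df.loc[0, "habitat_type"] = "tire_track"
    df.loc[1, "habitat_type"] = "man_made_pond"
    df.loc[2, "season"] = "DRY"
    out = filter_survey(df)
    assert len(out) == 3
    unchanged = filter_survey(survey_frame([0] * 4, list(range(4))))
    assert len(unchanged) == 4


def test_pod_degenerate_thresholds(small_sim):
    sat = small_sim["baseline"]["sat"]
    pts = survey_frame([1, 2, 3], [1, 2, 3])
    assert pod(sat, pts, 0.0, RAINY_WINDOW) == 1.0
    capped = SaturationCube(values=np.clip(sat.values, 0, 0.99),
                            dates=sat.dates)
    assert pod(capped, pts, 1.0, RAINY_WINDOW) == 0.0


def test_pod_matches_bruteforce_scan(small_sim):
    sat = small_sim["baseline"]["sat"]
    rng = np.random.default_rng(0)
    rows = rng.integers(0, sat.shape[1], 25)
    cols = rng.integers(0, sat.shape[2], 25)
    pts = survey_frame(rows, cols)
    theta = 0.5
    in_window = (sat.dates >= RAINY_WINDOW[0]) & (sat.dates <= RAINY_WINDOW[1])
    detected = 0
    for r, c in zip(rows, cols):
        detected += any(sat.values[np.asarray(in_window), r, c] >= theta)
    assert pod(sat, pts, theta, RAINY_WINDOW) == detected / 25


def test_pod_is_nonincreasing_in_theta(small_sim):
    sat = small_sim["baseline"]["sat"]
    rng = np.random.default_rng(1)
    pts = survey_frame(rng.integers(0, sat.shape[1], 40),
                       rng.integers(0, sat.shape[2], 40))
    pods = [pod(sat, pts, t, RAINY_WINDOW) for t in np.linspace(0, 1, 21)]
    assert np.all(np.diff(pods) <= 0)


def test_point_outside_grid_names_the_point(small_sim):
    pts = survey_frame([999], [0])
    with pytest.raises(ValueError, match="p0"):
        pod(small_sim["baseline"]["sat"], pts, 0.5, RAINY_WINDOW)


def test_single_point_theta_star_equals_its_max_saturation():
    """One point whose cell peaks at 0.60 calibrates theta* to 0.60."""
    values = np.full((365, 4, 4), 0.2)
    values[180:200, 2, 2] = 0.60
    sat = SaturationCube(values=values, dates=YEAR_DATES)
    result = calibrate_theta(sat, survey_frame([2], [2]),
                             theta_grid_step=0.01, n_bootstrap=10, seed=0)
    assert result.theta_star == pytest.approx(0.60)
    assert result.pod_calibration == 1.0


def test_selected_theta_is_largest_at_max_pod(small_sim, small_domain):
    sat = small_sim["baseline"]["sat"]
    survey = filter_survey(make_survey(sat, small_domain, theta_true=0.48,
                                       n_points=60, seed=2,
                                       frac_excluded_types=0.2))
    res = calibrate_theta(sat, survey, theta_grid_step=0.01,
                          n_bootstrap=100, seed=1)
    grid = np.array(sorted(res.pod_curve))
    pods = np.array([res.pod_curve[t] for t in grid])
    # any theta above theta_star on the grid loses POD on the full survey
    above = grid > res.theta_star + 1e-9
    assert np.all(pods[above] < res.pod_curve[res.theta_star] + 1e-12)


def test_threshold_recovery_single_replicate(small_sim, small_domain):
    sat = small_sim["baseline"]["sat"]
    survey = filter_survey(make_survey(sat, small_domain, theta_true=0.48,
                                       n_points=102, seed=5,
                                       frac_excluded_types=0.2))
    res = calibrate_theta(sat, survey, theta_grid_step=0.01,
                          n_bootstrap=200, seed=3)
    assert abs(res.theta_star - 0.48) <= 0.01
    assert res.pod_calibration == 1.0


def test_calibration_is_deterministic(small_sim, small_domain):
    sat = small_sim["baseline"]["sat"]
    survey = filter_survey(make_survey(sat, small_domain, theta_true=0.48,
                                       n_points=40, seed=5))
    a = calibrate_theta(sat, survey, n_bootstrap=1, seed=7)
    b = calibrate_theta(sat, survey, n_bootstrap=1, seed=7)
    assert a.theta_star == b.theta_star
    assert np.array_equal(a.bootstrap_thetas, b.bootstrap_thetas)


def test_empty_survey_rejected(small_sim):
    with pytest.raises(ValueError):
        calibrate_theta(small_sim["baseline"]["sat"],
                        pd.DataFrame(columns=["point_id", "row", "col",
                                              "season", "habitat_type",
                                              "larvae_present"]))
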