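import numpy as np
import pandas as pd
import pytest

from pondwi.cubes import FlowCube, WetnessCube
from pondwi.metrics import (SeasonDefinition, classify_stability,
                            coverage_series, exceedance_probability,
                            monthly_mean_coverage, stream_mask)

from conftest import YEAR_DATES


def wi_cube(values):
    values = np.asarray(values, dtype=np.int32)
    return WetnessCube(values=values, dates=YEAR_DATES[:values.shape[0]],
                       theta=0.48)


# ---------------------------------------------------------------- stream mask

def test_stream_mask_trivial_cases():
    zeros = FlowCube(values=np.zeros((365, 3, 3)), dates=YEAR_DATES)
    assert not stream_mask(zeros).any()
    fast = FlowCube(values=np.full((365, 3, 3), 0.02), dates=YEAR_DATES)
    assert stream_mask(fast).all()


def test_stream_mask_matches_day_counting():
    rng = np.random.default_rng(0)
    q = rng.exponential(0.01, (365, 6, 5))
    flow = FlowCube(values=q, dates=YEAR_DATES)
    got = stream_mask(flow, q_threshold=0.01, persistence=0.9)
    expect = np.zeros((6, 5), dtype=bool)
    for r in range(6):
        for c in range(5):
            expect[r, c] = (q[:, r, c] > 0.01).sum() >= 0.9 * 365
    assert np.array_equal(got, expect)


# ------------------------------------------------------------ exceedance maps

def test_always_ponded_cell_closed_form():
    wi = wi_cube(np.arange(1, 366).reshape(-1, 1, 1))
    p10 = exceedance_probability(wi, 10, "YEAR")
    p15 = exceedance_probability(wi, 15, "YEAR")
    assert p10.values[0, 0] == pytest.approx(355 / 365, abs=0)
    assert p15.values[0, 0] == pytest.approx(350 / 365, abs=0)


def test_zero_wi_gives_zero_probability():
    wi = wi_cube(np.zeros((365, 2, 2)))
    assert np.all(exceedance_probability(wi, 10, "YEAR").values == 0.0)


def test_exceedance_matches_bruteforce_and_identity():
    rng = np.random.default_rng(1)
    from pondwi.cubes import SaturationCube
    from pondwi.wetness import compute_wi
    sat = SaturationCube(values=rng.random((365, 5, 4)), dates=YEAR_DATES)
    wi = compute_wi(sat, 0.4)
    seasons = SeasonDefinition()
    maps = {p: exceedance_probability(wi, 10, p, seasons)
            for p in ("YEAR", "DRY", "RAINY")}
    months = wi.dates.month
    dry_days = int(np.isin(months, list(seasons.dry_months)).sum())
    rainy_days = 365 - dry_days
    for r in range(5):
        for c in range(4):
            series = wi.values[:, r, c]
            assert maps["YEAR"].values[r, c] == (series > 10).sum() / 365
            dry_sel = np.isin(months, list(seasons.dry_months))
            assert maps["DRY"].values[r, c] == \
                (series[dry_sel] > 10).sum() / dry_days
    # exact counting identity: year counts = dry counts + rainy counts
    lhs = maps["YEAR"].values * 365
    rhs = maps["DRY"].values * dry_days + maps["RAINY"].values * rainy_days
    assert np.allclose(lhs, rhs, rtol=0, atol=1e-9)


def test_masked_cells_are_missing_not_zero():
    wi = wi_cube(np.arange(1, 366).reshape(-1, 1, 1).repeat(2, 1))
    mask = np.array([[True], [False]])
    emap = exceedance_probability(wi, 10, "YEAR", mask=mask)
    assert np.isnan(emap.values[0, 0]) and emap.values[1, 0] > 0
    assert emap.mask_applied


def test_invalid_period_and_T():
    wi = wi_cube(np.zeros((365, 2, 2)))
    with pytest.raises(ValueError):
        exceedance_probability(wi, 0, "YEAR")
    with pytest.raises(ValueError):
        exceedance_probability(wi, 10, "MONSOON")


# ------------------------------------------------------------ coverage series

def test_coverage_direct_count():
    day = np.array([[11, 9], [20, 0]], dtype=np.int32)
    wi = wi_cube(day.reshape(1, 2, 2))
    region = np.ones((2, 2), dtype=bool)
    f = coverage_series(wi, 10, region)
    assert f.values[0] == 0.5
    # with T=0 the strict comparator counts currently ponded cells (WI >= 1)
    f0 = coverage_series(wi, 0, region)
    assert f0.values[0] == 0.75
    geq = coverage_series(wi, 10, region, comparator="geq")
    assert geq.values[0] == 0.5  # 11 and 20 only; 9 < 10


def test_coverage_matches_bruteforce():
    rng = np.random.default_rng(2)
    vals = rng.integers(0, 30, (90, 6, 6)).astype(np.int32)
    # make values valid WI-like (not required by the op, but realistic)
    wi = WetnessCube(values=vals, dates=YEAR_DATES[:90], theta=0.5)
    region = rng.random((6, 6)) < 0.5
    f = coverage_series(wi, 12, region)
    for t in (0, 45, 89):
        assert f.values[t] == (vals[t][region] > 12).mean()


def test_nesting_in_T():
    rng = np.random.default_rng(3)
    from pondwi.cubes import SaturationCube
    from pondwi.wetness import compute_wi
    sat = SaturationCube(values=rng.random((365, 5, 5)), dates=YEAR_DATES)
    wi = compute_wi(sat, 0.3)
    region = np.ones((5, 5), dtype=bool)
    f10 = coverage_series(wi, 10, region).values
    f15 = coverage_series(wi, 15, region).values
    assert np.all(f15 <= f10)
    p10 = exceedance_probability(wi, 10, "YEAR").values
    p15 = exceedance_probability(wi, 15, "YEAR").values
    assert np.all(p15 <= p10)


def test_empty_region_rejected():
    wi = wi_cube(np.zeros((10, 2, 2)))
    with pytest.raises(ValueError):
        coverage_series(wi, 10, np.zeros((2, 2), dtype=bool))


# ------------------------------------------------------------- monthly means

def test_monthly_mean_constant_series():
    wi = wi_cube(np.zeros((365, 1, 1)))
    series = coverage_series(wi, 10, np.ones((1, 1), dtype=bool))
    series.values[:] = 0.5
    out = monthly_mean_coverage(series)
    jan = out[out["month"] == 1].iloc[0]
    assert jan["mean"] == 0.5 and jan["ci95_low"] == jan["ci95_high"] == 0.5
    assert jan["n_days"] == 31 and bool(jan["complete"])


def test_monthly_mean_alternating_series():
    from pondwi.metrics import CoverageSeries
    vals = np.tile([0.0, 1.0], 15)
    series = CoverageSeries(values=vals, dates=YEAR_DATES[90:120], T=10)
    out = monthly_mean_coverage(series)
    row = out.iloc[0]
    assert row["mean"] == pytest.approx(0.5)
    sd = np.std(vals, ddof=1)
    assert sd == pytest.approx(0.5085, abs=1e-4)
    assert row["ci95_high"] - row["mean"] == pytest.approx(
        1.96 * sd / np.sqrt(30))


def test_partial_months_are_flagged():
    from pondwi.metrics import CoverageSeries
    series = CoverageSeries(values=np.full(40, 0.2), dates=YEAR_DATES[:40],
                            T=10)
    out = monthly_mean_coverage(series)
    assert bool(out[out["month"] == 1]["complete"].iloc[0]) is True
    assert bool(out[out["month"] == 2]["complete"].iloc[0]) is False


# ----------------------------------------------------------------- stability

@pytest.mark.parametrize("duration,expected", [
    (0, "NON_HABITAT"), (14, "NON_HABITAT"), (15, "TEMPORARY"),
    (89, "TEMPORARY"), (90, "SEMI_PERMANENT"), (179, "SEMI_PERMANENT"),
    (180, "PERMANENT"), (365, "PERMANENT"),
])
def test_stability_boundaries(duration, expected):
    from pondwi.metrics import STABILITY_CLASSES
    smap = classify_stability(np.array([[duration]]))
    assert STABILITY_CLASSES[int(smap.classes[0, 0])] == expected


def test_stability_fractions_sum_to_one_and_match_binning():
    rng = np.random.default_rng(4)
    durations = rng.integers(0, 400, (20, 20))
    smap = classify_stability(durations)
    assert sum(smap.fractions.values()) == pytest.approx(1.0, abs=1e-12)
    assert smap.histogram["count"].sum() == durations.size
    assert smap.histogram["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
    # brute-force one bin: [30, 45)
    row = smap.histogram[smap.histogram["bin_start"] == 30].iloc[0]
    assert row["count"] == ((durations >= 30) & (durations < 45)).sum()
    # open final bin
    top = smap.histogram.iloc[-1]
    assert top["bin_start"] == 360 and top["count"] == (durations >= 360).sum()


def test_stability_mask_and_negative_errors():
    durations = np.array([[20, 100], [200, 5]])
    mask = np.array([[True, False], [False, False]])
    smap = classify_stability(durations, mask=mask)
    assert smap.classes[0, 0] == 255
    assert sum(smap.fractions.values()) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        classify_stability(np.array([[-1]]))


def test_season_definition_partition_enforced():
    with pytest.raises(ValueError):
        SeasonDefinition(dry_months=frozenset({1, 2}),
                         rainy_months=frozenset({5, 6}))
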