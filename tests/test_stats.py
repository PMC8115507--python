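import numpy as np
import pytest
from scipy import stats as sps

from pondwi.metrics import CoverageSeries, ExceedanceMap
from pondwi.stats import (monthly_coverage_test, summarize_exceedance,
                          wilcoxon_increase_test)

from conftest import YEAR_DATES


def emap(values, T=10, period="YEAR"):
    return ExceedanceMap(values=np.asarray(values, dtype=float), T=T,
                         period=period)


def test_constant_map_summary():
    m = emap(np.full((4, 4), 0.4))
    out = summarize_exceedance(m, m, np.ones((4, 4), dtype=bool))
    row = out[out["scenario"] == "BASELINE"].iloc[0]
    assert row["mean"] == row["p25"] == row["median"] == row["p75"] == 0.4


def test_quantiles_use_linear_interpolation():
    m = emap(np.array([[0.0, 0.0], [1.0, 1.0]]))
    out = summarize_exceedance(m, m, np.ones((2, 2), dtype=bool))
    row = out.iloc[0]
    assert row["median"] == 0.5 and row["p25"] == 0.0 and row["p75"] == 1.0


def test_identical_maps_give_identical_rows():
    rng = np.random.default_rng(0)
    m = emap(rng.random((5, 5)))
    out = summarize_exceedance(m, m, np.ones((5, 5), dtype=bool))
    a, b = out.iloc[0], out.iloc[1]
    for col in ("mean", "p25", "median", "p75", "n_cells"):
        assert a[col] == b[col]


def test_masked_cells_are_dropped_from_summary():
    vals = np.array([[0.2, np.nan], [0.4, 0.6]])
    out = summarize_exceedance(emap(vals), emap(vals),
                               np.ones((2, 2), dtype=bool))
    assert out.iloc[0]["n_cells"] == 3
    with pytest.raises(ValueError):
        summarize_exceedance(emap(np.full((2, 2), np.nan)),
                             emap(np.full((2, 2), np.nan)),
                             np.ones((2, 2), dtype=bool))


def test_ranksum_exact_textbook_case():
    """Completely separated samples of 3: the most extreme of C(6,3)=20 orderings."""
    res = wilcoxon_increase_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert res.method == "exact"
    assert res.p_value == pytest.approx(0.05, abs=1e-12)


def test_ranksum_directionality():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, 50)
    same = wilcoxon_increase_test(base, base)
    assert same.p_value >= 0.5
    wrong = wilcoxon_increase_test(base + 5.0, base)
    assert wrong.p_value > 0.99


def test_ranksum_degenerate_flag():
    res = wilcoxon_increase_test([1.0, 1.0], [1.0, 1.0])
    assert res.degenerate and res.p_value == 0.5


def test_ranksum_exact_close_to_asymptotic_for_small_n():
    rng = np.random.default_rng(2)
    for _ in range(20):
        x = rng.normal(0, 1, rng.integers(4, 11))
        y = rng.normal(0.3, 1, rng.integers(4, 11))
        exact = sps.mannwhitneyu(y, x, alternative="greater",
                                 method="exact").pvalue
        approx = sps.mannwhitneyu(y, x, alternative="greater",
                                  method="asymptotic").pvalue
        assert abs(exact - approx) <= 0.02


def month_series(values, month_start_idx=0):
    return CoverageSeries(values=np.asarray(values, dtype=float),
                          dates=YEAR_DATES[month_start_idx:
                                           month_start_idx + len(values)],
                          T=10)


def test_t_test_identical_series_not_significant():
    rng = np.random.default_rng(3)
    vals = rng.random(31) * 0.2 + 0.4
    s = month_series(vals)
    res = monthly_coverage_test(s, s, month=1)
    assert not res.significant_at_0_01


def test_t_test_detects_constant_shift():
    rng = np.random.default_rng(4)
    base = rng.normal(0.3, 0.02, 31)
    irr = base + 0.3
    res = monthly_coverage_test(month_series(np.clip(base, 0, 1)),
                                month_series(np.clip(irr, 0, 1)), month=1)
    assert res.significant_at_0_01 and res.p_value < 1e-6


def test_t_statistic_matches_welch_formula():
    x = np.linspace(0.30, 0.45, 31)
    y = np.linspace(0.35, 0.60, 31)
    res = monthly_coverage_test(month_series(x), month_series(y), month=1)
    vx, vy = x.var(ddof=1) / 31, y.var(ddof=1) / 31
    t_hand = (y.mean() - x.mean()) / np.sqrt(vx + vy)
    assert res.t_stat == pytest.approx(t_hand, rel=1e-12)


def test_t_test_degenerate_zero_variance():
    s1 = month_series(np.full(31, 0.5))
    res = monthly_coverage_test(s1, month_series(np.full(31, 0.5)), month=1)
    assert res.degenerate and res.p_value == 0.5
    res2 = monthly_coverage_test(s1, month_series(np.full(31, 0.9)), month=1)
    assert res2.p_value == 0.0 and res2.significant_at_0_01


def test_partial_month_rejected():
    s = month_series(np.full(31, 0.5))
    partial = month_series(np.full(10, 0.5), month_start_idx=31)
    with pytest.raises(ValueError):
        monthly_coverage_test(s, partial, month=2)
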