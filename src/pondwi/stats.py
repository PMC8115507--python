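"""Scenario comparison statistics: summary tables and hypothesis tests.

Baseline vs irrigation comparisons use one-sided tests against the null
that irrigation did not increase the quantity: a Wilcoxon rank-sum test on
per-cell exceedance probabilities and a Welch two-sample t-test on daily
fractional-coverage values within a month.  Per-cell values are treated as
independent observations, mirroring the field's standard practice;
spatial autocorrelation is not corrected for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import CoverageSeries, ExceedanceMap

__all__ = ["RankSumResult", "TTestResult", "summarize_exceedance",
           "wilcoxon_increase_test", "monthly_coverage_test"]


@dataclass(frozen=True)
class RankSumResult:
    p_value: float
    statistic: float
    method: str          # "exact" or "asymptotic"
    degenerate: bool = False

    def __float__(self) -> float:
        return self.p_value


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    p_value: float
    significant_at_0_01: bool
    degenerate: bool = False


def summarize_exceedance(baseline: ExceedanceMap, irrigation: ExceedanceMap,
                         region_cells: np.ndarray,
                         region: str = "CUSTOM") -> pd.DataFrame:
    """Mean and quartiles of per-cell P over a region, for both scenarios.

    Returns two rows (baseline, irrigation) with mean, P25, median, P75 and
    the cell count, plus the one-sided rank-sum p-value for an
    irrigation-driven increase attached to both rows.  Quantiles use linear
    interpolation between order statistics.
    """
    if (baseline.T, baseline.period) != (irrigation.T, irrigation.period):
        raise ValueError("maps must share T and period")
    if baseline.values.shape != irrigation.values.shape:
        raise ValueError("maps must share the grid")
    region_cells = np.asarray(region_cells, dtype=bool)

    rows = []
    samples = {}
    for scenario, emap in (("BASELINE", baseline), ("IRRIGATION", irrigation)):
        vals = emap.values[region_cells]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"region empty after masking ({scenario})")
        samples[scenario] = vals
        rows.append({
            "region": region, "T": baseline.T, "period": baseline.period,
            "scenario": scenario,
            "mean": float(vals.mean()),
            "p25": float(np.percentile(vals, 25)),
            "median": float(np.percentile(vals, 50)),
            "p75": float(np.percentile(vals, 75)),
            "n_cells": int(vals.size),
        })
    test = wilcoxon_increase_test(samples["BASELINE"], samples["IRRIGATION"])
    out = pd.DataFrame(rows)
    out["wilcoxon_p"] = test.p_value
    return out


def wilcoxon_increase_test(baseline_values: np.ndarray,
                           irrigation_values: np.ndarray) -> RankSumResult:
    """One-sided rank-sum test: is the irrigation sample stochastically greater?

    Uses exact enumeration when both samples are small (n <= 20) and free
    of ties, and the tie-corrected normal approximation otherwise.  If all
    values across both samples are identical the comparison is degenerate
    and p = 0.5 is reported with a flag.
    """
    x = np.asarray(baseline_values, dtype=float).ravel()
    y = np.asarray(irrigation_values, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankSumResult(p_value=0.5, statistic=float(x.size * y.size / 2),
                             method="degenerate", degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(y, x, alternative="greater", method=method)
    return RankSumResult(p_value=float(res.pvalue),
                         statistic=float(res.statistic), method=method)


def _month_values(series: CoverageSeries, month: int) -> np.ndarray:
    sel = np.asarray(series.dates.month == month)
    if not sel.any():
        raise ValueError(f"series does not cover month {month}")
    years = series.dates.year[sel]
    full = pd.Period(f"{int(years[0])}-{month:02d}").days_in_month
    if sel.sum() < full:
        raise ValueError(f"series covers month {month} only partially")
    return series.values[sel]


def monthly_coverage_test(baseline_series: CoverageSeries,
                          irrigation_series: CoverageSeries,
                          month: int) -> TTestResult:
    """One-sided Welch t-test on a month's daily coverage values.

    Tests whether irrigation increased the month's fractional coverage;
    significance is flagged at the 0.01 level.  Two zero-variance samples
    with equal means are degenerate (p = 0.5).
    """
    x = _month_values(baseline_series, month)
    y = _month_values(irrigation_series, month)
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.mean(y) == np.mean(x):
            return TTestResult(t_stat=0.0, p_value=0.5,
                               significant_at_0_01=False, degenerate=True)
        p = 0.0 if np.mean(y) > np.mean(x) else 1.0
        t = np.inf if p == 0.0 else -np.inf
        return TTestResult(t_stat=t, p_value=p,
                           significant_at_0_01=p < 0.01, degenerate=True)
    res = sps.ttest_ind(y, x, equal_var=False, alternative="greater")
    return TTestResult(t_stat=float(res.statistic),
                       p_value=float(res.pvalue),
                       significant_at_0_01=bool(res.pvalue < 0.01))
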