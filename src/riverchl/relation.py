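"""Fluorescence-vs-concentration linear regression suite.

Ordinary least squares of buffer-median fluorescence (RFU, response) on
laboratory chlorophyll concentration (ug/L, predictor), fitted three ways:
pooled over everything, per site, and per day. Correlation strength is
summarized with adjusted r^2; group means are reported both raw and with
negative adjusted r^2 floored at zero. Slopes therefore carry units of RFU
per ug/L; users wanting the transposed orientation can invert the fit.

A sensitivity re-run excluding the highest-fluorescence matchups (by
default only the single maximum) quantifies the leverage of apparent
outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    """One fitted (or unfitted) simple linear regression."""

    scope: str  # "pooled", "site:<id>" or "day:<index>"
    n: int
    slope: float = np.nan
    intercept: float = np.nan
    r2: float = np.nan
    adj_r2: float = np.nan
    p_value: float = np.nan
    fitted: bool = False
    reason: str = ""

    @property
    def significant(self) -> bool:
        return self.fitted and self.p_value < 0.05


def fit_linear_relation(chl_ugL: np.ndarray, rfu: np.ndarray,
                        scope: str = "pooled") -> RegressionResult:
    """OLS of fluorescence on concentration with slope t-test.

    Requires at least 3 finite pairs and non-degenerate predictor variance;
    otherwise an unfitted result with a reason code is returned rather than
    raising, so grouped sweeps keep going.
    """
    x = np.asarray(chl_ugL, dtype=float)
    y = np.asarray(rfu, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        return RegressionResult(scope, n, reason="n < 3")
    if np.ptp(x) == 0.0:
        return RegressionResult(scope, n, reason="zero predictor variance")
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(scope, n, slope=float(res.slope),
                            intercept=float(res.intercept), r2=float(r2),
                            adj_r2=float(adj), p_value=float(res.pvalue),
                            fitted=True)


def _mean_adj_r2(results: list[RegressionResult]) -> tuple[float, float]:
    vals = np.array([r.adj_r2 for r in results if r.fitted])
    if vals.size == 0:
        return np.nan, np.nan
    return float(vals.mean()), float(np.maximum(vals, 0.0).mean())


def relation_suite(matches: pd.DataFrame) -> tuple[
        list[RegressionResult], dict]:
    """Pooled, per-site and per-day regressions over a field-lab table.

    ``matches`` needs columns site_id, day_index, chl_ugL, rfu_median.
    Returns the individual results plus a summary holding mean adjusted
    r^2 per grouping, computed raw and with negative values floored at
    zero, and significance counts at p < 0.05. Groups with fewer than 3
    pairs are listed unfitted and excluded from the means.
    """
    if len(matches) == 0:
        raise ValueError("empty matchup table")
    results = [fit_linear_relation(matches["chl_ugL"], matches["rfu_median"],
                                   "pooled")]
    site_res, day_res = [], []
    for site, grp in matches.groupby("site_id", sort=True):
        site_res.append(fit_linear_relation(
            grp["chl_ugL"], grp["rfu_median"], f"site:{site}"))
    for day, grp in matches.groupby("day_index", sort=True):
        day_res.append(fit_linear_relation(
            grp["chl_ugL"], grp["rfu_median"], f"day:{day}"))
    results += site_res + day_res

    pooled = results[0]
    summary = {
        "pooled_adj_r2": pooled.adj_r2,
        "pooled_slope": pooled.slope,
        "pooled_p_value": pooled.p_value,
        "site_mean_adj_r2": _mean_adj_r2(site_res)[0],
        "site_mean_adj_r2_floored": _mean_adj_r2(site_res)[1],
        "day_mean_adj_r2": _mean_adj_r2(day_res)[0],
        "day_mean_adj_r2_floored": _mean_adj_r2(day_res)[1],
        "n_sites_significant": sum(r.significant for r in site_res),
        "n_days_significant": sum(r.significant for r in day_res),
        "n_site_models": len(site_res),
        "n_day_models": len(day_res),
    }
    return results, summary


def sensitivity_excluding_max(matches: pd.DataFrame,
                              rfu_threshold: float | None = None) -> dict:
    """Re-run the suite without the highest-fluorescence rows.

    With no threshold, only the single maximum ``rfu_median`` row is
    excluded; otherwise all rows strictly above ``rfu_threshold`` go. The
    return bundles before/after results and per-scope deltas in adjusted
    r^2 and p.
    """
    if len(matches) == 0:
        raise ValueError("empty matchup table")
    before_res, before_sum = relation_suite(matches)
    if rfu_threshold is None:
        drop = matches["rfu_median"] == matches["rfu_median"].max()
        # exclude only one row even under exact ties
        drop = drop & (drop.cumsum() == 1)
    else:
        drop = matches["rfu_median"] > rfu_threshold
    reduced = matches[~drop]
    if len(reduced) == 0:
        raise ValueError("threshold excludes every row")
    after_res, after_sum = relation_suite(reduced)

    before_by = {r.scope: r for r in before_res}
    after_by = {r.scope: r for r in after_res}
    deltas = {}
    for scope, b in before_by.items():
        a = after_by.get(scope)
        if a is not None and a.fitted and b.fitted:
            deltas[scope] = {"d_adj_r2": a.adj_r2 - b.adj_r2,
                             "d_p_value": a.p_value - b.p_value}
    return {"n_excluded": int(drop.sum()),
            "before": before_res, "after": after_res,
            "before_summary": before_sum, "after_summary": after_sum,
            "deltas": deltas}


def results_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "scope": r.scope, "n": r.n, "slope": r.slope,
        "intercept": r.intercept, "r2": r.r2, "adj_r2": r.adj_r2,
        "p_value": r.p_value, "fitted": r.fitted,
        "significant": r.significant, "reason": r.reason,
    } for r in results])
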