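"""Model evaluation: error metrics, product ranking, variable importance.

Metrics are mean absolute error and bias, both in the response's native
units (RFU). Bias is signed as ``mean(prediction - observation)``, so
positive means overestimation. When aggregating across days, *absolute*
bias is averaged so opposite-signed daily biases do not cancel. Products
are compared by within-day ranks (1 = lowest MAE, ties averaged) whose
mean over days summarizes relative performance. Variable importance is the
forest's impurity decrease (permutation importance behind a flag),
converted to within-run ranks and summarized across the daily models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.inspection import permutation_importance

from .forest import ModelRun


@dataclass(frozen=True)
class EvalRecord:
    """Error metrics for one run (or one test day of the pooled run)."""

    day_index: int | None
    product_label: str
    model_type: str
    mae: float
    bias: float
    n_test: int

    @property
    def abs_bias(self) -> float:
        return abs(self.bias)


def compute_metrics(run: ModelRun, use_edm: bool = True) -> EvalRecord:
    """MAE and signed bias of one run's test predictions.

    EDM-corrected predictions are used by default; pass ``use_edm=False``
    for the raw forest output.
    """
    pred = run.y_pred_edm if use_edm else run.y_pred_raw
    obs = run.y_obs
    if pred.shape != obs.shape:
        raise ValueError("prediction/observation length mismatch")
    if obs.size == 0:
        raise ValueError("empty test vectors")
    err = pred - obs
    return EvalRecord(run.day_index, run.product_label, run.model_type,
                      float(np.abs(err).mean()), float(err.mean()), obs.size)


def metrics_table(runs: list[ModelRun], use_edm: bool = True) -> pd.DataFrame:
    recs = [compute_metrics(r, use_edm) for r in runs]
    return pd.DataFrame([{
        "day_index": r.day_index, "product_label": r.product_label,
        "model_type": r.model_type, "mae": r.mae, "bias": r.bias,
        "abs_bias": r.abs_bias, "n_test": r.n_test} for r in recs])


def aggregate_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per model-type x product summary of MAE and bias magnitude.

    Mean and median are taken across days, with the absolute value of bias
    taken *before* averaging. The pooled model has a single run per
    product, so its row carries raw values, not aggregates.
    """
    if len(records) == 0:
        raise ValueError("no evaluation records")
    rows = []
    for (mtype, product), grp in records.groupby(
            ["model_type", "product_label"], sort=True):
        ab = grp["bias"].abs()
        rows.append({
            "model_type": mtype, "product_label": product,
            "mean_mae": grp["mae"].mean(), "median_mae": grp["mae"].median(),
            "mean_abs_bias": ab.mean(), "median_abs_bias": ab.median(),
            "n_days": len(grp)})
    return pd.DataFrame(rows)


def rank_products(records: pd.DataFrame, key: str = "mae") -> tuple[
        pd.DataFrame, pd.DataFrame]:
    """Within-day product ranks and their means across days.

    Within each (day, model type) cell, products are ranked ascending on
    ``key`` (``mae`` or ``abs_bias``) with average ranks on ties, so three
    products always sum to 6. Days missing a product are excluded from
    that grouping with a log-free NaN-safe drop. Returns (per-day rank
    table, mean rank per model type x product).
    """
    if key not in ("mae", "abs_bias"):
        raise ValueError("key must be 'mae' or 'abs_bias'")
    df = records.dropna(subset=["day_index"]).copy()
    n_products = df["product_label"].nunique()
    rows = []
    for (day, mtype), grp in df.groupby(["day_index", "model_type"],
                                        sort=True):
        if grp["product_label"].nunique() < n_products:
            continue
        ranks = stats.rankdata(grp[key].to_numpy(), method="average")
        for (_, rec), rk in zip(grp.iterrows(), ranks):
            rows.append({"day_index": day, "model_type": mtype,
                         "product_label": rec["product_label"],
                         "rank": float(rk)})
    per_day = pd.DataFrame(rows)
    if len(per_day) == 0:
        raise ValueError("no complete day x model_type cells to rank")
    mean_rank = (per_day.groupby(["model_type", "product_label"],
                                 sort=True)["rank"]
                 .mean().reset_index(name="mean_rank"))
    return per_day, mean_rank


def importance_ranks(run: ModelRun, use_permutation: bool = False,
                     X: np.ndarray | None = None,
                     y: np.ndarray | None = None,
                     seed: int = 0) -> np.ndarray:
    """Within-run importance ranks, 1 = most important, ties averaged."""
    if use_permutation:
        if run.model is None or X is None or y is None:
            raise ValueError("permutation importance needs the fitted model "
                             "and evaluation data")
        imp = permutation_importance(run.model, X, y, n_repeats=5,
                                     random_state=seed).importances_mean
    else:
        imp = run.importances
    if imp is None:
        raise ValueError("run has no importances")
    return stats.rankdata(-np.asarray(imp), method="average")


def aggregate_importance(runs: list[ModelRun]) -> pd.DataFrame:
    """Distribution of importance ranks per index across daily models.

    Accepts the individual-day runs for one product; each run contributes
    one rank per index (1 = most important). Returns median and quartiles
    per index, sorted by median rank.
    """
    daily = [r for r in runs if r.importances is not None]
    if len(daily) < 2:
        raise ValueError("need at least 2 daily runs with importances")
    names = daily[0].feature_names
    rank_rows = np.stack([importance_ranks(r) for r in daily])
    out = pd.DataFrame({
        "index": names,
        "median_rank": np.median(rank_rows, axis=0),
        "q1_rank": np.percentile(rank_rows, 25, axis=0),
        "q3_rank": np.percentile(rank_rows, 75, axis=0),
        "mean_rank": rank_rows.mean(axis=0),
        "n_models": len(daily)})
    return out.sort_values("median_rank", kind="stable").reset_index(drop=True)
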