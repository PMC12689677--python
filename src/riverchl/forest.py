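"""Random-forest harness for the three-way model evaluation design.

Three model configurations are trained per satellite product, all sharing
the same per-day 75/25 stratified splits so their error metrics are
directly comparable:

* ``individual`` — one forest per survey day, trained on that day's 75%;
* ``loo`` — leave-one-day-out: one forest per day, trained on *all* rows
  (train and test portions) of every other day, tested on the held day's
  25% only — emulating application to an unseen date;
* ``pooled`` — a single forest trained on the union of all days' 75%
  portions, tested on each day's 25%.

Supporting machinery: quantile-stratified splitting of the response,
spatially clustered cross-validation folds (k-means on position) for
hyperparameter tuning, and empirical-distribution-matching (EDM) bias
correction — a quantile mapping that gives predictions the ECDF of the
training-set observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product as iproduct

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor

from .indices import index_names

logger = logging.getLogger("riverchl")

MODEL_TYPES = ("individual", "loo", "pooled")


@dataclass(frozen=True)
class HyperParams:
    """Forest hyperparameters exposed to tuning."""

    n_trees: int = 300
    max_depth: int | None = None  # None = unlimited
    m_vars: int = 8  # predictors tried per split

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (1 <= self.m_vars <= 16):
            raise ValueError("m_vars must lie in [1, 16]")

    def _sort_key(self) -> tuple:
        depth = np.inf if self.max_depth is None else self.max_depth
        return (self.n_trees, depth, self.m_vars)


def default_grid() -> list[HyperParams]:
    return [HyperParams(t, d, m)
            for t, d, m in iproduct((100, 300, 500), (4, 8, None), (4, 8, 16))]


@dataclass
class ModelRun:
    """One trained-and-tested forest with raw and EDM-corrected predictions."""

    model_type: str
    product_label: str
    day_index: int | None  # None for the pooled aggregate run
    test_row_ids: np.ndarray
    test_day_labels: np.ndarray
    y_obs: np.ndarray
    y_pred_raw: np.ndarray
    y_pred_edm: np.ndarray
    hyperparams: HyperParams
    seed: int
    feature_names: list[str]
    importances: np.ndarray
    edm_reference: np.ndarray = field(repr=False)
    model: RandomForestRegressor | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# splitting


def stratified_split(rfu: np.ndarray, frac: float = 0.75, n_bins: int = 10,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray, int]:
    """Quantile-stratified train/test split of one day's rows.

    Rows are binned by response quantiles (bins auto-collapsed when rows
    are few or values tie); within bins of >= 4 rows, ``frac`` go to train
    with largest-remainder rounding so the global fraction is honored to
    within a row or two; rows in smaller bins are pooled and allocated
    round-robin at the same fraction. Returns (train positions, test
    positions, bins actually used).
    """
    rfu = np.asarray(rfu, dtype=float)
    n = rfu.size
    if n < 4:
        raise ValueError(f"need at least 4 rows to split, got {n}")
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    eff_bins = max(1, min(n_bins, n // 4))
    if eff_bins < n_bins:
        logger.debug("collapsing %d bins to %d for %d rows",
                     n_bins, eff_bins, n)
    labels = np.asarray(pd.qcut(rfu, eff_bins, labels=False,
                                duplicates="drop"), dtype=float)
    # constant responses collapse every quantile edge; use a single bin
    labels = np.where(np.isnan(labels), 0.0, labels).astype(int)

    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    small_pool: list[np.ndarray] = []
    big: list[np.ndarray] = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        (big if members.size >= 4 else small_pool).append(members)

    if big:
        sizes = np.array([m.size for m in big])
        target_total = int(round(frac * sizes.sum()))
        ideal = frac * sizes
        base = np.floor(ideal).astype(int)
        remainder = target_total - base.sum()
        order = np.argsort(-(ideal - base))
        counts = base.copy()
        counts[order[:remainder]] += 1
        for members, k in zip(big, counts):
            perm = rng.permutation(members)
            train.append(perm[:k])
            test.append(perm[k:])

    if small_pool:
        pool = rng.permutation(np.concatenate(small_pool))
        period = max(2, int(round(1.0 / (1.0 - frac))))
        sel = (np.arange(pool.size) % period) != (period - 1)
        train.append(pool[sel])
        test.append(pool[~sel])

    train_idx = np.sort(np.concatenate(train)) if train else np.array([], int)
    test_idx = np.sort(np.concatenate(test)) if test else np.array([], int)
    return train_idx, test_idx, eff_bins


def make_split_plan(df: pd.DataFrame, frac: float = 0.75, n_bins: int = 10,
                    seed: int = 0, min_rows: int = 8) -> dict[int, dict]:
    """Per-day stratified splits for one product's matchup table.

    Keys are day indices; values hold positional ``train``/``test`` arrays
    into ``df`` (assumed RangeIndex) and the bin count used. Days with
    fewer than ``min_rows`` rows are skipped with a log entry (e.g. days
    clouded out of the satellite record).
    """
    plan: dict[int, dict] = {}
    for day, grp in df.groupby("day_index", sort=True):
        pos = grp.index.to_numpy()
        if pos.size < min_rows:
            logger.warning("day %s has %d matchup rows (< %d); skipped",
                           day, pos.size, min_rows)
            continue
        day_seed = np.random.SeedSequence([seed, int(day)]).generate_state(1)[0]
        tr, te, bins = stratified_split(grp["rfu"].to_numpy(), frac, n_bins,
                                        int(day_seed))
        plan[int(day)] = {"train": pos[tr], "test": pos[te], "n_bins": bins}
    return plan


# ---------------------------------------------------------------------------
# spatial folds and tuning


def spatial_folds(xy: np.ndarray, k: int = 8, seed: int = 0) -> np.ndarray:
    """Cluster observation locations into k cross-validation folds.

    Centroid-based (k-means) partitioning with seeded initialization;
    every point is labeled and folds are non-empty. Spatially blocked
    folds reduce the optimism that spatial autocorrelation lends to
    random-fold cross-validation.
    """
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    if k > n:
        raise ValueError(f"cannot form {k} folds from {n} points")
    if k == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=4, random_state=seed % (2 ** 31))
    return km.fit_predict(xy)


def tune_hyperparameters(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
                         grid: list[HyperParams] | None = None,
                         seed: int = 0) -> HyperParams:
    """Grid search minimizing mean held-fold MAE over the spatial folds.

    Ties break toward fewer trees, then shallower depth, then smaller
    ``m_vars`` (the grid is scanned in that order and only strict
    improvements replace the incumbent).
    """
    grid = default_grid() if grid is None else list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    fold_ids = np.unique(folds)
    if fold_ids.size < 2:
        raise ValueError("need at least 2 folds present for tuning")
    best: HyperParams | None = None
    best_mae = np.inf
    for hp in sorted(grid, key=HyperParams._sort_key):
        maes = []
        for f in fold_ids:
            held = folds == f
            model = _make_forest(hp, seed)
            model.fit(X[~held], y[~held])
            maes.append(np.abs(model.predict(X[held]) - y[held]).mean())
        mean_mae = float(np.mean(maes))
        if mean_mae < best_mae:
            best, best_mae = hp, mean_mae
    assert best is not None
    return best


def _make_forest(hp: HyperParams, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=hp.n_trees, max_depth=hp.max_depth,
        max_features=hp.m_vars, random_state=seed % (2 ** 31), n_jobs=1)


# ---------------------------------------------------------------------------
# EDM bias correction


def edm_correct(raw_predictions: np.ndarray,
                reference_observations: np.ndarray) -> np.ndarray:
    """Quantile-map predictions onto the reference distribution.

    Each raw prediction is assigned its plotting-position quantile
    ``p = (rank - 0.5) / n`` (average ranks on ties), then mapped to the
    reference empirical quantile at ``p`` by linear interpolation between
    order statistics (clamped at the extremes). The output is a monotone
    remap of the input: the weak ordering of predictions is preserved,
    while their ECDF becomes that of the reference.
    """
    raw = np.asarray(raw_predictions, dtype=float)
    ref = np.asarray(reference_observations, dtype=float)
    if raw.size == 0 or ref.size == 0:
        raise ValueError("raw and reference vectors must be nonempty")
    if not (np.isfinite(raw).all() and np.isfinite(ref).all()):
        raise ValueError("non-finite values in EDM inputs")
    p = (stats.rankdata(raw, method="average") - 0.5) / raw.size
    ref_sorted = np.sort(ref)
    q = (np.arange(1, ref.size + 1) - 0.5) / ref.size
    return np.interp(p, q, ref_sorted)


# ---------------------------------------------------------------------------
# study runner


def _run_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0]
               % (2 ** 31))


def _fit_and_record(model_type: str, product: str, day: int | None,
                    df: pd.DataFrame, feature_names: list[str],
                    train_ids: np.ndarray, test_ids: np.ndarray,
                    hp: HyperParams, seed: int, tune: bool,
                    grid: list[HyperParams] | None, n_folds: int,
                    keep_models: bool) -> ModelRun:
    Xtr = df.loc[train_ids, feature_names].to_numpy()
    ytr = df.loc[train_ids, "rfu"].to_numpy()
    Xte = df.loc[test_ids, feature_names].to_numpy()
    yte = df.loc[test_ids, "rfu"].to_numpy()
    if tune:
        xy = df.loc[train_ids, ["x", "y"]].to_numpy()
        k = min(n_folds, len(train_ids))
        folds = spatial_folds(xy, k, seed)
        hp = tune_hyperparameters(Xtr, ytr, folds, grid, seed)
    model = _make_forest(hp, seed)
    model.fit(Xtr, ytr)
    raw = model.predict(Xte)
    corrected = edm_correct(raw, ytr)
    return ModelRun(
        model_type=model_type, product_label=product, day_index=day,
        test_row_ids=np.asarray(test_ids),
        test_day_labels=df.loc[test_ids, "day_index"].to_numpy(),
        y_obs=yte, y_pred_raw=raw, y_pred_edm=corrected,
        hyperparams=hp, seed=seed, feature_names=list(feature_names),
        importances=model.feature_importances_.copy(),
        edm_reference=ytr.copy(),
        model=model if keep_models else None)


def run_study(matchups: dict[str, pd.DataFrame],
              model_types: tuple[str, ...] = MODEL_TYPES,
              seed: int = 0,
              split_plans: dict[str, dict[int, dict]] | None = None,
              params: HyperParams | None = None,
              tune: bool = False,
              grid: list[HyperParams] | None = None,
              n_folds: int = 8,
              frac: float = 0.75,
              n_bins: int = 10,
              keep_models: bool = False) -> list[ModelRun]:
    """Train and test every requested model over every product.

    ``matchups`` maps product label -> field-satellite matchup table (with
    ``day_index``, ``rfu``, ``x``, ``y`` and the registry index columns).
    One master ``seed`` expands deterministically into per-run seeds. The
    per-day test sets are identical across the three model types by
    construction. Returns one :class:`ModelRun` per (product, day) for the
    individual and LOO types plus one pooled run per product — 3 x (11 +
    11 + 1) = 69 runs for an 11-day, 3-product study.
    """
    unknown = set(model_types) - set(MODEL_TYPES)
    if unknown:
        raise ValueError(f"unknown model types: {sorted(unknown)}")
    hp = params or HyperParams()
    feature_names = index_names()
    runs: list[ModelRun] = []
    for p_idx, (product, df) in enumerate(sorted(matchups.items())):
        df = df.reset_index(drop=True)
        missing = [f for f in feature_names if f not in df.columns]
        if missing:
            raise ValueError(
                f"matchup table for {product} lacks index columns {missing}")
        if split_plans is not None and product in split_plans:
            plan = split_plans[product]
        else:
            plan = make_split_plan(df, frac, n_bins,
                                   _run_seed(seed, p_idx, 99))
        days = sorted(plan)
        if not days:
            logger.warning("product %s has no usable days; skipped", product)
            continue

        if "individual" in model_types:
            for day in days:
                runs.append(_fit_and_record(
                    "individual", product, day, df, feature_names,
                    plan[day]["train"], plan[day]["test"], hp,
                    _run_seed(seed, p_idx, 0, day), tune, grid, n_folds,
                    keep_models))
        if "loo" in model_types:
            if len(days) < 2:
                logger.warning("LOO undefined with a single day; skipped")
            else:
                for day in days:
                    other = np.concatenate(
                        [np.concatenate([plan[d]["train"], plan[d]["test"]])
                         for d in days if d != day])
                    runs.append(_fit_and_record(
                        "loo", product, day, df, feature_names,
                        np.sort(other), plan[day]["test"], hp,
                        _run_seed(seed, p_idx, 1, day), tune, grid, n_folds,
                        keep_models))
        if "pooled" in model_types:
            train = np.sort(np.concatenate([plan[d]["train"] for d in days]))
            test = np.sort(np.concatenate([plan[d]["test"] for d in days]))
            runs.append(_fit_and_record(
                "pooled", product, None, df, feature_names, train, test, hp,
                _run_seed(seed, p_idx, 2), tune, grid, n_folds, keep_models))
    return runs
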