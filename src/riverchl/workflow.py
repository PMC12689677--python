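"""End-to-end study orchestration.

``run_full_study`` chains the stages — simulate, match, regress, fit all
model types over all products, evaluate, map — into a single report, with
every source of randomness derived from one master seed so reruns are
reproducible. ``StudyConfig`` gathers each stage's parameter block and
round-trips through YAML unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluate import (aggregate_importance, aggregate_table, metrics_table,
                       rank_products)
from .forest import MODEL_TYPES, HyperParams, run_study
from .mapping import predict_scene, variability_summary
from .matchup import match_study
from .relation import relation_suite, results_to_frame
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger("riverchl")


@dataclass(frozen=True)
class StudyConfig:
    """Full configuration of one synthetic-study run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    radius_km: float = 0.4
    max_latency_days: int = 3
    split_frac: float = 0.75
    split_bins: int = 10
    model_types: tuple[str, ...] = MODEL_TYPES
    hyperparams: HyperParams = field(default_factory=HyperParams)
    tune: bool = False
    n_folds: int = 8
    map_product: str | None = None  # default: first product label
    seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        d = yaml.safe_load(text) or {}
        sim = d.pop("simulation", {})
        if sim.get("grid_shape") is not None:
            sim["grid_shape"] = tuple(sim["grid_shape"])
        if "product_labels" in sim:
            sim["product_labels"] = tuple(sim["product_labels"])
        hp = d.pop("hyperparams", {})
        if "model_types" in d:
            d["model_types"] = tuple(d["model_types"])
        return cls(simulation=SimulationConfig(**sim),
                   hyperparams=HyperParams(**hp), **d)

    def with_seed(self, seed: int) -> "StudyConfig":
        return dataclasses.replace(
            self, seed=seed,
            simulation=dataclasses.replace(self.simulation, seed=seed))


def run_full_study(config: StudyConfig, out_dir: Path | None = None) -> dict:
    """Execute the whole pipeline and return (optionally persist) a report.

    Stages: simulate -> matchup -> regression suite -> forest study (all
    model types x products) -> metrics / ranks / importance -> scene
    mapping with the individual-day models -> variability summary.
    """
    t0 = time.time()
    logger.info("simulating study (seed=%d)", config.simulation.seed)
    tracks, samples, scenes, states = simulate_study(config.simulation)

    logger.info("matching field, lab and satellite observations")
    sat_matchups, lab_matches = match_study(
        tracks, samples, scenes, config.max_latency_days, config.radius_km)
    if not sat_matchups:
        raise RuntimeError("no field-satellite matchups produced")

    logger.info("fitting fluorescence-concentration regressions")
    fitted = lab_matches[lab_matches["n_points"] > 0]
    relation_results, relation_summary = relation_suite(fitted)

    logger.info("training forests: %s x %s", config.model_types,
                sorted(sat_matchups))
    runs = run_study(sat_matchups, config.model_types, seed=config.seed,
                     params=config.hyperparams, tune=config.tune,
                     n_folds=config.n_folds, frac=config.split_frac,
                     n_bins=config.split_bins, keep_models=True)

    records = metrics_table(runs)
    table = aggregate_table(records)
    rank_day, rank_mean = rank_products(records)

    map_product = config.map_product or sorted(sat_matchups)[0]
    daily_runs = [r for r in runs
                  if r.model_type == "individual"
                  and r.product_label == map_product]
    importance = aggregate_importance(daily_runs) if len(daily_runs) >= 2 \
        else None

    logger.info("mapping scenes for product %s", map_product)
    rasters = []
    for run in daily_runs:
        scene = next((s for s in scenes
                      if s.day_index == run.day_index
                      and s.product_label == map_product), None)
        if scene is not None:
            rasters.append(predict_scene(scene, run))
    variability = variability_summary(rasters) if len(rasters) >= 2 else None

    report = {
        "config": config,
        "n_runs": len(runs),
        "runs": runs,
        "relation_results": results_to_frame(relation_results),
        "relation_summary": relation_summary,
        "metrics": records,
        "aggregate": table,
        "rank_per_day": rank_day,
        "rank_mean": rank_mean,
        "importance": importance,
        "variability": variability,
        "manifest": {
            "seed": config.seed,
            "version": __version__,
            "n_runs": len(runs),
            "model_types": list(config.model_types),
            "products": sorted(sat_matchups),
            "n_days": int(lab_matches["day_index"].nunique()),
            "elapsed_s": round(time.time() - t0, 2),
        },
    }
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(report["config"].to_yaml())
    report["relation_results"].to_csv(out_dir / "relation_results.csv",
                                      index=False)
    report["metrics"].to_csv(out_dir / "metrics.csv", index=False)
    report["aggregate"].to_csv(out_dir / "aggregate.csv", index=False)
    report["rank_per_day"].to_csv(out_dir / "rank_per_day.csv", index=False)
    report["rank_mean"].to_csv(out_dir / "rank_mean.csv", index=False)
    if report["importance"] is not None:
        report["importance"].to_csv(out_dir / "importance.csv", index=False)
    summary = {"relation_summary": _jsonable(report["relation_summary"]),
               "manifest": report["manifest"]}
    if report["variability"] is not None:
        v = dict(report["variability"])
        v["per_date"] = v["per_date"].to_dict(orient="records")
        summary["variability"] = _jsonable(v)
    (out_dir / "report.json").write_text(json.dumps(summary, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
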