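"""Whole-scene prediction and spatial-vs-temporal variability summaries.

A fitted run is applied to every valid (water, cloud-free) pixel of a
scene, producing a fluorescence raster; masked cells carry NaN. A stack of
such rasters is then summarized to compare within-day spatial variability
(mean of per-date SDs) against total variability across space and time
(pooled SD) — their ratio is the temporal-dominance indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .forest import ModelRun, edm_correct
from .indices import VariantFlags, compute_indices
from .simulate import SceneStack

logger = logging.getLogger("riverchl")


@dataclass
class PredictionRaster:
    """Per-cell predicted fluorescence (RFU) on valid cells, NaN elsewhere."""

    day_index: int
    product_label: str
    model_type: str
    values: np.ndarray
    transform: tuple[float, float, float]

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def predict_scene(scene: SceneStack, run: ModelRun, apply_edm: bool = True,
                  erode_shoreline: bool = False,
                  flags: VariantFlags | None = None) -> PredictionRaster:
    """Apply a fitted run to all valid pixels of a scene.

    Indices are computed per valid cell in the run's feature order, the
    forest is applied, and (optionally) EDM remaps the predictions using
    the run's training reference. ``erode_shoreline`` shrinks the mask by
    one cell before prediction to suppress shoreline anomalies; it is off
    by default.
    """
    if run.model is None:
        raise ValueError("run does not retain its fitted model "
                         "(re-run with keep_models=True)")
    missing = [b for b in ("b2", "b3", "b4", "b5", "b6", "b8a")
               if b not in scene.bands]
    if missing:
        raise ValueError(f"scene is missing bands: {missing}")
    mask = scene.mask
    if erode_shoreline:
        mask = ndimage.binary_erosion(mask)
    out = np.full(scene.shape, np.nan)
    if mask.any():
        bands = {b: scene.bands[b][mask].astype(float)
                 for b in scene.bands}
        idx = compute_indices(bands, flags)
        X = np.column_stack([idx[name] for name in run.feature_names])
        pred = run.model.predict(X)
        if apply_edm:
            pred = edm_correct(pred, run.edm_reference)
        out[mask] = pred
    return PredictionRaster(scene.day_index, scene.product_label,
                            run.model_type, out, scene.transform)


def variability_summary(rasters: list[PredictionRaster]) -> dict:
    """Spatial-vs-temporal variability over a stack of prediction rasters.

    Per date: SD (ddof=1), median and range over valid cells. Overall:
    the mean of per-date SDs (typical within-day spatial variability), the
    pooled SD of all valid cells of all dates, and their ratio — a ratio
    above 1 means day-to-day variability exceeds within-day spatial
    variability. Rasters with fewer than 2 valid cells are excluded.
    """
    if len(rasters) < 2:
        raise ValueError("need at least 2 rasters")
    per_date = []
    all_vals = []
    for r in rasters:
        vals = r.valid_values
        if vals.size < 2:
            logger.warning("raster day=%s product=%s has %d valid cells; "
                           "excluded", r.day_index, r.product_label,
                           vals.size)
            continue
        per_date.append({"day_index": r.day_index,
                         "product_label": r.product_label,
                         "sd": float(np.std(vals, ddof=1)),
                         "median": float(np.median(vals)),
                         "range": float(np.ptp(vals)),
                         "n_valid": vals.size})
        all_vals.append(vals)
    if len(per_date) < 2:
        raise ValueError("fewer than 2 rasters with >= 2 valid cells")
    pooled = np.concatenate(all_vals)
    per_date_df = pd.DataFrame(per_date)
    mean_sd = float(per_date_df["sd"].mean())
    pooled_sd = float(np.std(pooled, ddof=1))
    return {"per_date": per_date_df,
            "mean_of_per_date_sd": mean_sd,
            "mean_of_per_date_range": float(per_date_df["range"].mean()),
            "pooled_sd": pooled_sd,
            "pooled_range": float(np.ptp(pooled)),
            "temporal_spatial_ratio": pooled_sd / mean_sd if mean_sd > 0
            else np.inf}
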