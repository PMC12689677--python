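"""Joins across the three observation scales.

Two matchups are produced:

* field -> satellite: every boat-survey fluorescence observation is paired
  with the single pixel of the single scene (per product) closest in time
  within a +/-3 calendar-day window, and the spectral indices are computed
  for that pixel;
* field -> laboratory: every discrete lab sample is paired with the median
  (and min/max) fluorescence of all track points within a 0.4-km
  straight-line buffer of the site.

All distances are planar Euclidean in the shared metric CRS. Latency is
signed (image date minus survey date); ties between equally distant scenes
break toward the earlier image.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .indices import VariantFlags, compute_indices
from .simulate import BANDS, LabSample, SceneStack, SurveyTrack


def locate_cell(scene: SceneStack, x: float | np.ndarray,
                y: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row/col of the cell whose footprint contains (x, y)."""
    x0, y0, cell = scene.transform
    col = np.floor((np.asarray(x) - x0) / cell).astype(int)
    row = np.floor((np.asarray(y) - y0) / cell).astype(int)
    return row, col


def extract_pixel(scene: SceneStack, x: float, y: float) -> dict | None:
    """Band values of the single cell containing (x, y).

    Returns ``None`` (the invalid marker) if that cell is masked. Raises if
    the point lies outside the raster extent. No neighborhood averaging.
    """
    row, col = locate_cell(scene, x, y)
    rows, cols = scene.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(
            f"point ({x}, {y}) falls outside the raster extent "
            f"({rows} x {cols} cells)")
    if not scene.mask[row, col]:
        return None
    return {b: float(scene.bands[b][row, col]) for b in BANDS}


def _select_scene(scenes: list[SceneStack], survey_date: int,
                  max_latency_days: int) -> SceneStack | None:
    """Scene with minimal |image - survey| latency; ties toward earlier."""
    best = None
    for sc in scenes:
        lat = sc.date_ordinal - survey_date
        if abs(lat) > max_latency_days:
            continue
        if best is None:
            best = sc
            continue
        blat = best.date_ordinal - survey_date
        if (abs(lat), sc.date_ordinal) < (abs(blat), best.date_ordinal):
            best = sc
    return best


def match_field_satellite(track: SurveyTrack, scenes: list[SceneStack],
                          max_latency_days: int = 3,
                          flags: VariantFlags | None = None) -> pd.DataFrame:
    """Pair each track point with its containing pixel, per product.

    For each product label among ``scenes``, the single scene with minimal
    absolute latency within the window is used; points on masked cells or
    outside the raster are dropped. Returns one row per retained
    (point, product) pair with columns: day_index, product_label, row_id,
    x, y, rfu, latency_days, the six bands, and every registry index.
    """
    products = sorted({s.product_label for s in scenes})
    out_frames = []
    for product in products:
        cand = [s for s in scenes if s.product_label == product]
        scene = _select_scene(cand, track.date_ordinal, max_latency_days)
        if scene is None:
            continue
        latency = scene.date_ordinal - track.date_ordinal
        xs = track.data["x"].to_numpy()
        ys = track.data["y"].to_numpy()
        row, col = locate_cell(scene, xs, ys)
        rows, cols = scene.shape
        inside = (row >= 0) & (row < rows) & (col >= 0) & (col < cols)
        valid = inside.copy()
        valid[inside] = scene.mask[row[inside], col[inside]]
        if not valid.any():
            continue
        r, c = row[valid], col[valid]
        bands = {b: scene.bands[b][r, c].astype(float) for b in BANDS}
        idx = compute_indices(bands, flags)
        df = pd.DataFrame({
            "day_index": track.day_index,
            "product_label": product,
            "row_id": np.nonzero(valid)[0],
            "x": xs[valid], "y": ys[valid],
            "rfu": track.data["rfu"].to_numpy()[valid],
            "latency_days": latency,
        })
        for b in BANDS:
            df[b] = bands[b]
        for name, vals in idx.items():
            df[name] = vals
        out_frames.append(df)
    if not out_frames:
        return pd.DataFrame(columns=["day_index", "product_label", "row_id",
                                     "x", "y", "rfu", "latency_days"])
    return pd.concat(out_frames, ignore_index=True)


def match_field_lab(track: SurveyTrack, samples: list[LabSample],
                    radius_km: float = 0.4) -> pd.DataFrame:
    """Buffer-median aggregation of track fluorescence around each site.

    For every same-day sample, all track points within ``radius_km``
    (inclusive boundary, straight-line distance) contribute; the median,
    min and max RFU and the in-buffer point count are reported. Samples
    with zero in-buffer points are returned flagged (``n_points == 0``,
    NaN statistics), never silently dropped.
    """
    radius_m = radius_km * 1000.0
    xs = track.data["x"].to_numpy()
    ys = track.data["y"].to_numpy()
    rfu = track.data["rfu"].to_numpy()
    rows = []
    for s in samples:
        if s.day_index != track.day_index:
            continue
        dist = np.hypot(xs - s.x, ys - s.y)
        sel = dist <= radius_m
        n = int(sel.sum())
        if n:
            vals = rfu[sel]
            med, lo, hi = (float(np.median(vals)), float(vals.min()),
                           float(vals.max()))
        else:
            med = lo = hi = math.nan
        rows.append({"site_id": s.site_id, "day_index": s.day_index,
                     "chl_ugL": s.chl_ugL, "rfu_median": med,
                     "rfu_min": lo, "rfu_max": hi, "n_points": n})
    return pd.DataFrame(rows, columns=["site_id", "day_index", "chl_ugL",
                                       "rfu_median", "rfu_min", "rfu_max",
                                       "n_points"])


def match_study(tracks: list[SurveyTrack], samples: list[LabSample],
                scenes: list[SceneStack], max_latency_days: int = 3,
                radius_km: float = 0.4,
                flags: VariantFlags | None = None
                ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Run both matchups over a whole study.

    Returns (field-satellite tables keyed by product label, field-lab
    table). Days with no usable scene for a product simply contribute no
    rows for that product.
    """
    sat_frames = []
    lab_frames = []
    for track in tracks:
        sat_frames.append(match_field_satellite(
            track, [s for s in scenes], max_latency_days, flags))
        lab_frames.append(match_field_lab(track, samples, radius_km))
    sat = pd.concat([f for f in sat_frames if len(f)], ignore_index=True) \
        if any(len(f) for f in sat_frames) else pd.DataFrame()
    by_product = {}
    if len(sat):
        for product, grp in sat.groupby("product_label"):
            by_product[str(product)] = grp.reset_index(drop=True)
    lab = pd.concat(lab_frames, ignore_index=True) if lab_frames \
        else pd.DataFrame()
    return by_product, lab
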