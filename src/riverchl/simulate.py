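"""Seeded synthetic river study generator.

Emulates the data structure of a multi-scale river chlorophyll campaign:
longitudinal boat-survey fluorescence tracks (one per survey day), discrete
laboratory chlorophyll samples at fixed sites, and per-day multiband
reflectance scenes in several satellite product flavours (AR / SR / TOA)
sharing one water mask.

The generative model encodes the empirical structure the analysis assumes:

* a positive, spatially autocorrelated latent chlorophyll field along the
  channel (log-Gaussian, Ornstein-Uhlenbeck along channel distance) whose
  day-level log-mean varies with SD ``day_mean_log_sd`` — by default well
  above the within-day spatial log-SD, so temporal variability dominates
  spatial variability;
* a day-specific fluorescence yield (RFU per ug/L) with coefficient of
  variation ``yield_cv``, which makes the pooled RFU-concentration relation
  weak while per-day relations stay strong;
* a red-edge reflectance peak: band b5 rises monotonically with chlorophyll
  while b4 and b6 respond only weakly; each product label then applies its
  own per-day per-band affine (gain, offset) perturbation plus sensor noise,
  emulating day-to-day atmospheric variation and product-to-product
  differences;
* contiguous cloud patches masking an expected fraction of the water cells.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy.random.Generator`` (PCG64), so outputs are bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

BANDS = ("b2", "b3", "b4", "b5", "b6", "b8a")

#: Baseline water-leaving reflectance per band (dimensionless).
_BAND_BASE = {"b2": 0.025, "b3": 0.030, "b4": 0.020,
              "b5": 0.018, "b6": 0.012, "b8a": 0.008}
#: Reflectance increase per ug/L chlorophyll: strong red-edge response in
#: b5, weak responses elsewhere.
_BAND_SLOPE = {"b2": 0.00002, "b3": 0.00008, "b4": 0.00005,
               "b5": 0.00080, "b6": 0.00010, "b8a": 0.00004}

_EPOCH = pd.Timestamp("2021-08-01")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults mirror the study design being emulated: 11 survey days, tracks
    sampled every 15 s (~600 points/day), a 220-km reach on a 20-m grid,
    10 lab-sampling sites, and three satellite product labels.
    """

    n_days: int = 11
    n_track_points_per_day: int = 600
    channel_length_km: float = 220.0
    grid_shape: tuple[int, int] | None = None  # derived from channel if None
    cell_size_m: float = 20.0
    n_sites: int = 10
    chl_log_mean: float = math.log(3.0)  # ug/L, day-level centre
    day_mean_log_sd: float = 0.6
    along_channel_corr_length_km: float = 30.0
    within_day_log_sd: float = 0.25
    yield_rfu_per_ugL: float = 0.23
    yield_cv: float = 0.8
    background_rfu: float = 0.2
    background_cv: float = 0.6
    rfu_noise_cv: float = 0.08
    lab_noise_cv: float = 0.05
    min_reporting_ugL: float = 0.10
    product_labels: tuple[str, ...] = ("AR", "SR", "TOA")
    atm_gain_sd: float = 0.03
    atm_offset_sd: float = 0.0005
    sensor_noise_sd: float = 0.001
    cloud_fraction: float = 0.10
    day_spacing_days: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {"n_days": self.n_days, "n_sites": self.n_sites,
                  "n_track_points_per_day": self.n_track_points_per_day,
                  "day_spacing_days": self.day_spacing_days}
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        scales = {"channel_length_km": self.channel_length_km,
                  "cell_size_m": self.cell_size_m,
                  "day_mean_log_sd": self.day_mean_log_sd,
                  "along_channel_corr_length_km":
                      self.along_channel_corr_length_km,
                  "within_day_log_sd": self.within_day_log_sd,
                  "yield_rfu_per_ugL": self.yield_rfu_per_ugL,
                  "yield_cv": self.yield_cv,
                  "background_rfu": self.background_rfu,
                  "background_cv": self.background_cv,
                  "rfu_noise_cv": self.rfu_noise_cv,
                  "lab_noise_cv": self.lab_noise_cv,
                  "atm_gain_sd": self.atm_gain_sd,
                  "atm_offset_sd": self.atm_offset_sd,
                  "sensor_noise_sd": self.sensor_noise_sd}
        for name, v in scales.items():
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.channel_length_km <= 0 or self.cell_size_m <= 0:
            raise ValueError("channel_length_km and cell_size_m must be > 0")
        if not (0.0 <= self.cloud_fraction < 1.0):
            raise ValueError("cloud_fraction must lie in [0, 1)")
        if self.grid_shape is not None:
            rows, cols = self.grid_shape
            if rows < 8 or cols < 8:
                raise ValueError("grid_shape must be at least 8 x 8")
            if cols * self.cell_size_m < self.channel_length_km * 1000.0:
                raise ValueError(
                    "grid columns do not span channel_length_km at this "
                    "cell size")

    @property
    def resolved_grid_shape(self) -> tuple[int, int]:
        if self.grid_shape is not None:
            return self.grid_shape
        cols = int(math.ceil(self.channel_length_km * 1000.0
                             / self.cell_size_m))
        return (24, cols)


@dataclass
class LatentRiverState:
    """Per-day hidden truth behind all observables."""

    day_index: int
    date_ordinal: int
    image_date_ordinal: int
    chl_true: np.ndarray  # per along-channel column, ug/L
    yield_day: float  # RFU per ug/L
    background_day: float  # additive fluorescence background, RFU
    atm_params: dict[str, dict[str, tuple[float, float]]]  # product->band->(g,o)


@dataclass
class SurveyTrack:
    """One survey day of ordered, geolocated fluorescence observations."""

    day_index: int
    date_ordinal: int
    data: pd.DataFrame  # columns: timestamp, x, y, rfu


@dataclass
class LabSample:
    """One discrete laboratory chlorophyll sample."""

    site_id: str
    day_index: int
    x: float
    y: float
    chl_ugL: float


@dataclass
class SceneStack:
    """Multiband reflectance raster plus validity mask for one day/product."""

    day_index: int
    product_label: str
    date_ordinal: int
    bands: dict[str, np.ndarray]  # float32, shape (rows, cols)
    mask: np.ndarray  # bool, True = valid water pixel
    transform: tuple[float, float, float]  # (x_origin, y_origin, cell_size)
    crs: str = "local-metre"

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


class _ChannelGeometry:
    """Gently sinuous channel rasterized onto the common grid.

    Channel distance is taken as the x coordinate (sinuosity is mild), the
    centerline meanders in y, and the water mask is a constant-width ribbon
    around it.
    """

    def __init__(self, config: SimulationConfig):
        rows, cols = config.resolved_grid_shape
        cell = config.cell_size_m
        self.rows, self.cols, self.cell = rows, cols, cell
        self.length_m = config.channel_length_km * 1000.0
        self.col_x = (np.arange(cols) + 0.5) * cell
        amp_rows = rows * 0.15
        wavelength = max(self.length_m / 8.0, 20 * cell)
        self.center_row = (rows / 2.0
                           + amp_rows * np.sin(2 * np.pi * self.col_x
                                               / wavelength))
        self.halfwidth_rows = max(2, rows // 4)
        row_idx = np.arange(rows)[:, None]
        self.water = (np.abs(row_idx + 0.5 - self.center_row[None, :])
                      <= self.halfwidth_rows)
        # columns beyond the channel end are dry land
        self.water[:, self.col_x > self.length_m] = False

    def center_y(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.col_x, self.center_row) * self.cell

    def col_of(self, s: np.ndarray) -> np.ndarray:
        return np.clip((np.asarray(s) // self.cell).astype(int),
                       0, self.cols - 1)


def _ou_field(rng: np.random.Generator, n: int, dx: float,
              corr_length: float, sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path on a regular 1-D grid."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    phi = math.exp(-dx / corr_length) if corr_length > 0 else 0.0
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal(n)
    f = np.empty(n)
    f[0] = sd * eps[0]
    for k in range(1, n):
        f[k] = phi * f[k - 1] + innov_sd * eps[k]
    return f


def _cloud_mask(rng: np.random.Generator, water: np.ndarray,
                fraction: float, cell: float) -> np.ndarray:
    """Contiguous elliptical cloud patches covering ~`fraction` of water."""
    rows, cols = water.shape
    cloud = np.zeros_like(water, dtype=bool)
    if fraction <= 0.0:
        return cloud
    n_water = int(water.sum())
    target = fraction * n_water
    rr, cc = np.mgrid[0:rows, 0:cols]
    for _ in range(1000):
        if (cloud & water).sum() >= target:
            break
        r0 = rng.uniform(0, rows)
        c0 = rng.uniform(0, cols)
        # clouds are broad relative to the channel's cross-section
        ry = rng.uniform(rows * 0.5, rows * 2.0)
        rx = rng.uniform(rows * 2.0, rows * 12.0)
        cloud |= ((rr - r0) / ry) ** 2 + ((cc - c0) / rx) ** 2 <= 1.0
    return cloud


_LATENCY_CHOICES = np.array([0, 0, 0, 0, 0, 0, 0, 0, -1, -2, -3])


def simulate_study(config: SimulationConfig) -> tuple[
        list[SurveyTrack], list[LabSample], list[SceneStack],
        list[LatentRiverState]]:
    """Run the forward model for one full synthetic study.

    Returns one track, up to ``n_sites`` lab samples, and one scene per
    product label, for each of ``n_days`` days, along with the latent states
    that generated them. Deterministic for a fixed config (same seed twice
    gives bit-identical output).
    """
    geom = _ChannelGeometry(config)
    rng = np.random.default_rng(config.seed)
    rows, cols = geom.rows, geom.cols
    cell = geom.cell

    tracks: list[SurveyTrack] = []
    samples: list[LabSample] = []
    scenes: list[SceneStack] = []
    states: list[LatentRiverState] = []

    site_s = (np.arange(config.n_sites) + 0.5) / config.n_sites * geom.length_m
    site_y = geom.center_y(site_s)

    yield_sigma = math.sqrt(math.log1p(config.yield_cv ** 2))
    bg_sigma = math.sqrt(math.log1p(config.background_cv ** 2))

    for d in range(config.n_days):
        date_ord = d * config.day_spacing_days
        latency = int(rng.choice(_LATENCY_CHOICES))
        image_ord = date_ord + latency

        # latent chlorophyll field along channel distance
        mu_day = rng.normal(0.0, config.day_mean_log_sd)
        f = _ou_field(rng, cols, cell,
                      config.along_channel_corr_length_km * 1000.0,
                      config.within_day_log_sd)
        chl_col = np.exp(config.chl_log_mean + mu_day + f)

        yield_day = config.yield_rfu_per_ugL * math.exp(
            rng.normal(0.0, yield_sigma) - 0.5 * yield_sigma ** 2)
        # day-varying additive optical background (fDOM / turbidity matrix
        # effects on the fluorometer); zero when background_rfu == 0
        bg_day = config.background_rfu * math.exp(
            rng.normal(0.0, bg_sigma) - 0.5 * bg_sigma ** 2) \
            if config.background_rfu > 0 else 0.0

        atm: dict[str, dict[str, tuple[float, float]]] = {}
        for product in config.product_labels:
            atm[product] = {
                b: (1.0 + rng.normal(0.0, config.atm_gain_sd),
                    rng.normal(0.0, config.atm_offset_sd))
                for b in BANDS}

        states.append(LatentRiverState(d, date_ord, image_ord,
                                       chl_col, yield_day, bg_day, atm))

        # ---- boat survey track
        n_pts = config.n_track_points_per_day
        s = np.linspace(0.02, 0.98, n_pts) * geom.length_m
        # boat stays in the shipping channel: small transverse offset
        max_off = max(geom.halfwidth_rows - 1.5, 0.5) * cell
        offset = rng.uniform(-max_off, max_off, n_pts)
        x = s
        y = geom.center_y(s) + offset
        chl_at = np.interp(s, geom.col_x, chl_col)
        rfu = yield_day * chl_at * (
            1.0 + config.rfu_noise_cv * rng.standard_normal(n_pts)) + bg_day
        rfu = np.maximum(rfu, 0.0)
        t0 = _EPOCH + pd.Timedelta(days=date_ord, hours=10)
        timestamps = t0 + pd.to_timedelta(np.arange(n_pts) * 15, unit="s")
        tracks.append(SurveyTrack(
            d, date_ord,
            pd.DataFrame({"timestamp": timestamps, "x": x, "y": y,
                          "rfu": rfu})))

        # ---- lab samples at fixed sites
        chl_sites = np.interp(site_s, geom.col_x, chl_col)
        lab = chl_sites * (1.0 + config.lab_noise_cv
                           * rng.standard_normal(config.n_sites))
        lab = np.maximum(lab, config.min_reporting_ugL)
        for i in range(config.n_sites):
            samples.append(LabSample(f"site{i + 1:02d}", d,
                                     float(site_s[i]), float(site_y[i]),
                                     float(lab[i])))

        # ---- scenes, one per product, sharing the day's cloud field
        cloud = _cloud_mask(rng, geom.water, config.cloud_fraction, cell)
        mask = geom.water & ~cloud
        base = {b: _BAND_BASE[b] + _BAND_SLOPE[b] * chl_col for b in BANDS}
        for product in config.product_labels:
            bands = {}
            for b in BANDS:
                gain, off = atm[product][b]
                plane = gain * base[b][None, :] + off
                plane = np.broadcast_to(plane, (rows, cols)).copy()
                if config.sensor_noise_sd > 0:
                    plane += rng.normal(0.0, config.sensor_noise_sd,
                                        (rows, cols))
                bands[b] = plane.astype(np.float32)
            scenes.append(SceneStack(d, product, image_ord, bands,
                                     mask.copy(), (0.0, 0.0, cell)))

    return tracks, samples, scenes, states


# ---------------------------------------------------------------------------
# fixture I/O


def tracks_to_frame(tracks: list[SurveyTrack]) -> pd.DataFrame:
    frames = []
    for t in tracks:
        df = t.data.copy()
        df.insert(0, "date_index", t.day_index)
        df.insert(1, "date_ordinal", t.date_ordinal)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def samples_to_frame(samples: list[LabSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"site_id": s.site_id, "date_index": s.day_index,
          "x": s.x, "y": s.y, "chl_ugL": s.chl_ugL} for s in samples])


def write_scene(scene: SceneStack, path: Path) -> None:
    """Write a scene as a multi-page TIFF (6 band planes + mask plane) with
    a JSON sidecar holding the geotransform and labels."""
    stack = np.stack([scene.bands[b] for b in BANDS], axis=0)
    tifffile.imwrite(path, stack)
    tifffile.imwrite(path, scene.mask.astype(np.uint8), append=True)
    meta = {"day_index": scene.day_index, "product_label": scene.product_label,
            "date_ordinal": scene.date_ordinal, "bands": list(BANDS),
            "transform": list(scene.transform), "crs": scene.crs}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_scene(path: Path) -> SceneStack:
    meta = json.loads(Path(str(path) + ".json").read_text())
    with tifffile.TiffFile(path) as tif:
        stack = tif.series[0].asarray()
        mask = tif.series[1].asarray().astype(bool)
    bands = {b: stack[i] for i, b in enumerate(meta["bands"])}
    return SceneStack(meta["day_index"], meta["product_label"],
                      meta["date_ordinal"], bands, mask,
                      tuple(meta["transform"]), meta["crs"])


def write_fixtures(tracks: list[SurveyTrack], samples: list[LabSample],
                   scenes: list[SceneStack], directory: Path,
                   seed: int | None = None) -> dict:
    """Persist a simulated study as CSV + TIFF files and return the manifest.

    The manifest lists one entry per written data file:
    ``n_days * (1 track + 1 sample table + n_products scenes)``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    track_by_day = {t.day_index: t for t in tracks}
    days = sorted(track_by_day)
    samples_df = samples_to_frame(samples) if samples else pd.DataFrame(
        columns=["site_id", "date_index", "x", "y", "chl_ugL"])
    for d in days:
        t = track_by_day[d]
        tpath = directory / f"track_day{d:02d}.csv"
        df = t.data.copy()
        df.insert(0, "date_index", d)
        df.to_csv(tpath, index=False)
        entries.append({"kind": "track", "day_index": d, "path": tpath.name})

        spath = directory / f"samples_day{d:02d}.csv"
        samples_df[samples_df.date_index == d].to_csv(spath, index=False)
        entries.append({"kind": "samples", "day_index": d,
                        "path": spath.name})

        for scene in (s for s in scenes if s.day_index == d):
            scpath = directory / f"scene_day{d:02d}_{scene.product_label}.tif"
            write_scene(scene, scpath)
            entries.append({"kind": "scene", "day_index": d,
                            "product_label": scene.product_label,
                            "path": scpath.name})
    manifest = {"seed": seed, "n_days": len(days), "entries": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_fixtures(directory: Path) -> tuple[
        list[SurveyTrack], list[LabSample], list[SceneStack]]:
    """Load a study previously persisted by :func:`write_fixtures`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    tracks, samples, scenes = [], [], []
    for entry in manifest["entries"]:
        path = directory / entry["path"]
        if entry["kind"] == "track":
            df = pd.read_csv(path, parse_dates=["timestamp"])
            date_ord = int((df["timestamp"].iloc[0].normalize()
                            - _EPOCH).days)
            tracks.append(SurveyTrack(
                int(entry["day_index"]), date_ord,
                df[["timestamp", "x", "y", "rfu"]].reset_index(drop=True)))
        elif entry["kind"] == "samples":
            for _, r in pd.read_csv(path).iterrows():
                samples.append(LabSample(str(r.site_id), int(r.date_index),
                                         float(r.x), float(r.y),
                                         float(r.chl_ugL)))
        elif entry["kind"] == "scene":
            scenes.append(read_scene(path))
    return tracks, samples, scenes
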