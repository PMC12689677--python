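import numpy as np
import pandas as pd
import pytest

from riverchl.indices import compute_indices, index_names
from riverchl.simulate import SimulationConfig, simulate_study


def small_config(**overrides) -> SimulationConfig:
    """A fast, fully featured study configuration for unit tests."""
    defaults = dict(
        n_days=4, n_track_points_per_day=150, channel_length_km=40.0,
        along_channel_corr_length_km=8.0, n_sites=6, cloud_fraction=0.08,
        seed=11)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """One simulated small study shared across read-only tests."""
    cfg = small_config()
    tracks, samples, scenes, states = simulate_study(cfg)
    return cfg, tracks, samples, scenes, states


def synthetic_matchups(n_days=5, rows_per_day=60,
                       products=("AR", "SR", "TOA"), seed=0,
                       signal="b5") -> dict[str, pd.DataFrame]:
    """Build field-satellite matchup tables directly from random band sets.

    The response is a noisy monotone function of the chosen band, with a
    day-specific affine distortion, so forests have something learnable
    without running the full simulator.
    """
    rng = np.random.default_rng(seed)
    tables = {}
    for product in products:
        frames = []
        for day in range(n_days):
            bands = {b: rng.uniform(0.005, 0.08, rows_per_day)
                     for b in ("b2", "b3", "b4", "b5", "b6", "b8a")}
            idx = compute_indices(bands)
            gain = rng.uniform(0.6, 1.4)
            rfu = gain * 20.0 * bands[signal] + 0.1 * rng.standard_normal(
                rows_per_day)
            df = pd.DataFrame({"day_index": day,
                               "x": rng.uniform(0, 5000, rows_per_day),
                               "y": rng.uniform(0, 500, rows_per_day),
                               "rfu": np.maximum(rfu, 0.0)})
            for name in index_names():
                df[name] = idx[name]
            frames.append(df)
        tables[product] = pd.concat(frames, ignore_index=True)
    return tables


def planted_mci_matchups(n_days=5, rows_per_day=80, seed=0,
                         product="AR") -> dict[str, pd.DataFrame]:
    """Matchups whose response is driven through the MCI bands alone.

    A latent signal u enters b5 and b6 antisymmetrically around a strongly
    varying common level c, so the red-edge peak height S05 = b5 - b6
    recovers u exactly while every other index is dominated by c or by
    independent band noise.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for day in range(n_days):
        c = rng.uniform(0.02, 0.12, rows_per_day)
        u = rng.uniform(0.001, 0.04, rows_per_day)
        bands = {"b2": rng.uniform(0.01, 0.1, rows_per_day),
                 "b3": rng.uniform(0.01, 0.1, rows_per_day),
                 "b4": rng.uniform(0.01, 0.1, rows_per_day),
                 "b5": c + u / 2.0, "b6": c - u / 2.0,
                 "b8a": rng.uniform(0.01, 0.1, rows_per_day)}
        idx = compute_indices(bands)
        rfu = 30.0 * u + 0.02 * rng.standard_normal(rows_per_day)
        df = pd.DataFrame({"day_index": day,
                           "x": rng.uniform(0, 5000, rows_per_day),
                           "y": rng.uniform(0, 500, rows_per_day),
                           "rfu": np.maximum(rfu, 0.0)})
        for name in index_names():
            df[name] = idx[name]
        frames.append(df)
    return {product: pd.concat(frames, ignore_index=True)}
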