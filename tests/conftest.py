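"""Shared fixtures: small seeded synthetic sessions and PSD builders."""
from __future__ import annotations

import numpy as np
import pytest

from eegperf import (PSDTimeSeries, BehaviorSeries, SimConfig, simulate_session,
                     compute_psd, smooth_psd, lane_deviation_series)

TINY_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "O2", "T7")


def tiny_config(**overrides) -> SimConfig:
    from dataclasses import replace

    base = SimConfig(
        channel_names=TINY_CHANNELS, n_blocks=3, block_len=180.0,
        break_len=20.0,
        coupling=(("Oz", "alpha", 0.4), ("O2", "alpha", 0.4),
                  ("Fz", "theta", -0.4), ("Cz", "theta", -0.4)))
    return replace(base, **overrides) if overrides else base


@pytest.fixture(scope="session")
def tiny_session():
    """One small coupled driving session plus its smoothed PSD and target."""
    cfg = tiny_config()
    bundle = simulate_session(cfg, 42, task="driving")
    psd = smooth_psd(compute_psd(bundle.eeg), block_bounds=cfg.block_bounds)
    lane = lane_deviation_series(bundle.vehicle, block_bounds=cfg.block_bounds,
                                 epoch_times=psd.epoch_times,
                                 epoch_blocks=psd.block_ids)
    return cfg, bundle, psd, lane


def synthetic_psd(rng, n_channels=4, n_blocks=3, epochs_per_block=60,
                  couple=None, noise=0.05, latent=None, step=2.0):
    """Directly construct a PSDTimeSeries with optional planted coupling.

    ``couple`` maps channel index -> (band bin slice, gain); the same
    latent series (returned) drives every coupled channel. Much faster
    than synthesizing raw EEG for algorithm-level tests.
    """
    n = n_blocks * epochs_per_block
    if latent is None:
        # smooth latent: cumulative sum re-standardized, then lightly smoothed
        z = np.cumsum(rng.standard_normal(n))
        z = (z - z.mean()) / z.std()
        kernel = np.ones(9) / 9.0
        latent = np.convolve(z, kernel, mode="same")
        latent = (latent - latent.mean()) / latent.std()
    logpower = 3.0 + noise * rng.standard_normal((n, n_channels, 40))
    if couple:
        for ci, (bins, gain) in couple.items():
            logpower[:, ci, bins] += gain * latent[:, None]
    times = []
    blocks = []
    for b in range(n_blocks):
        t0 = b * (epochs_per_block * step + 30.0)
        times.append(t0 + np.arange(epochs_per_block) * step)
        blocks.append(np.full(epochs_per_block, b))
    channel_names = [f"ch{i}" for i in range(n_channels)]
    psd = PSDTimeSeries(logpower, np.arange(1, 41, dtype=float),
                        np.concatenate(times), channel_names,
                        np.concatenate(blocks))
    return psd, np.asarray(latent)


def behavior_from_latent(psd, latent, rng=None, noise=0.0, name="metric"):
    values = latent.copy()
    if noise and rng is not None:
        values = values + noise * rng.standard_normal(latent.size)
    return BehaviorSeries(name, psd.epoch_times, values, psd.block_ids)
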