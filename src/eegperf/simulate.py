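"""Synthetic sessions: EEG, driving logs and RSVP streams driven by a
shared latent alertness state.

The generative model is deliberately simple and fully seeded:

* a latent alertness state follows an Ornstein-Uhlenbeck process (time
  constant 120 s by default, standardized per session) — slow and
  mean-reverting, so most of its power survives the 90 s smoother;
* each EEG channel is 1/f background noise plus band-limited theta/alpha/
  beta oscillations; on "informative" channels the band amplitude is
  modulated so that band log10 power moves linearly with the latent state
  (gain in log10-power units per latent s.d.);
* lane-keeping error is an AR(1) wander whose innovation scale grows with
  the latent state (drowsier -> larger deviations);
* RSVP responses follow a logistic hit model with per-image perceptual
  difficulty shared across simulated participants (so grand-average
  normalization can remove it), latent-dependent reaction times and press
  durations, and a small latent-dependent false-alarm rate.

This simulator is the test harness for the estimation pipeline, not a
biophysical claim: there is no volume conduction, no eye/muscle artifact
structure, and oscillatory amplitudes are stationary apart from the
latent modulation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

from .containers import (ALPHA_BAND, BETA_BAND, BIOSEMI32, EEGRecording,
                         THETA_BAND)
from .errors import ParameterError

BANDS = {"theta": THETA_BAND, "alpha": ALPHA_BAND, "beta": BETA_BAND}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic session."""

    channel_names: tuple = BIOSEMI32
    fs: float = 256.0
    n_blocks: int = 6
    block_len: float = 600.0
    break_len: float = 60.0

    # latent alertness (Ornstein-Uhlenbeck, sampled at 1 Hz)
    ou_tau: float = 120.0          # mean-reversion time constant, s
    ou_sigma: float = 1.0          # stationary standard deviation
    ou_drift: float = 0.0          # optional within-block linear drift, s.d./block

    # EEG composition (amplitudes in microvolts)
    background_scale: float = 12.0
    background_exponent: float = 1.0
    osc_amplitudes: tuple = (("theta", 6.0), ("alpha", 8.0), ("beta", 4.0))
    #: channel -> (band, gain); gain is d(log10 band power)/d(latent s.d.)
    coupling: tuple = (("Oz", "alpha", 0.35), ("O2", "alpha", 0.35),
                       ("Fz", "theta", -0.35), ("Cz", "theta", -0.35))

    # driving
    vehicle_fs: float = 100.0
    lane_tau: float = 2.0          # AR(1) time constant, s
    lane_base_sd: float = 0.35     # stationary |offset| scale at latent 0, m
    lane_latent_gain: float = 0.5  # relative innovation-scale change per s.d.

    # RSVP
    rsvp_rate: float = 5.0
    blink_period: float = 10.0
    target_probs: tuple = (0.01, 0.03, 0.05, 0.07, 0.09, 0.11)
    target_classes: tuple = ("stair", "container", "poster", "chair", "door")
    images_per_class: int = 50
    class_difficulty: tuple = (0.8, 0.3, 1.2, -0.8, -0.4)  # per-class mean
    image_difficulty_sd: float = 0.6
    stimulus_seed: int = 20260926  # shared across participants (same image pool)

    hit_intercept: float = 2.2
    hit_latent_slope: float = 0.9   # logit units per latent s.d.
    hit_difficulty_slope: float = 1.0
    rt_base_ms: float = 520.0
    rt_latent_ms: float = 60.0
    rt_difficulty_ms: float = 40.0
    rt_noise_ms: float = 60.0
    duration_base_ms: float = 260.0
    duration_latent_ms: float = 45.0
    duration_noise_ms: float = 40.0
    fa_intercept: float = -5.0
    fa_latent_slope: float = 0.4

    def __post_init__(self):
        if self.fs <= 0 or self.block_len <= 0 or self.n_blocks < 1:
            raise ParameterError("rates and lengths must be positive")
        if any(not 0 < p < 1 for p in self.target_probs):
            raise ParameterError("target probabilities must lie in (0, 1)")

    @property
    def block_bounds(self) -> list[tuple[float, float]]:
        step = self.block_len + self.break_len
        return [(i * step, i * step + self.block_len) for i in range(self.n_blocks)]

    @property
    def session_end(self) -> float:
        return self.block_bounds[-1][1]

    @property
    def informative_channels(self) -> tuple:
        return tuple(ch for ch, _, g in self.coupling if g != 0.0)

    def coupling_map(self) -> dict:
        return {ch: (band, gain) for ch, band, gain in self.coupling}


@dataclass
class GroundTruth:
    """What the simulator actually generated, for recovery tests."""

    latent_times: np.ndarray
    latent: np.ndarray
    informative_channels: tuple
    coupling: dict
    block_bounds: list
    target_prob_by_block: dict | None = None
    target_class_by_block: dict | None = None
    image_difficulty: dict | None = None


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_latent(config: SimConfig, seed) -> tuple[np.ndarray, np.ndarray]:
    """OU alertness path on a 1 Hz grid spanning the session (standardized)."""
    rng = _rng(seed)
    t = np.arange(0.0, config.session_end + 1.0)
    theta = 1.0 / config.ou_tau
    phi = np.exp(-theta)  # dt = 1 s
    innov_sd = config.ou_sigma * np.sqrt(1 - phi**2)
    shocks = innov_sd * rng.standard_normal(t.size)
    shocks[0] = config.ou_sigma * rng.standard_normal()
    x = signal.lfilter([1.0], [1.0, -phi], shocks)
    if config.ou_drift != 0.0:
        for lo, hi in config.block_bounds:
            sel = (t >= lo) & (t < hi)
            x[sel] += config.ou_drift * (t[sel] - lo) / config.block_len
    sd = x.std()
    if sd > 0:
        x = (x - x.mean()) / sd
    return t, x


def _shaped_noise(rng, n, shape_mask):
    """Gaussian noise with the given one-sided amplitude spectrum, unit sd."""
    spec = (rng.standard_normal(n // 2 + 1).astype(np.float32)
            + 1j * rng.standard_normal(n // 2 + 1).astype(np.float32))
    x = sp_fft.irfft(spec * shape_mask.astype(np.complex64), n=n)
    return x / x.std()


def _pink_shape(n, fs, exponent):
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(f, f[1]) ** (-exponent / 2.0)
    shape[0] = 0.0
    return shape.astype(np.float32)


def _band_shape(n, fs, band, edge=1.0):
    """Brick-wall band mask with raised-cosine transitions (``edge`` Hz)."""
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = band
    mask = np.zeros_like(f)
    mask[(f >= lo) & (f <= hi)] = 1.0
    rise = (f >= lo - edge) & (f < lo)
    mask[rise] = 0.5 * (1 + np.cos(np.pi * (lo - f[rise]) / edge))
    fall = (f > hi) & (f <= hi + edge)
    mask[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi) / edge))
    return mask.astype(np.float32)


def simulate_eeg(config: SimConfig, latent_times, latent, seed) -> EEGRecording:
    """Synthesize the multichannel recording block by block.

    The returned array spans the whole session timeline (sample index =
    time * fs); inter-block break periods carry no signal and are never
    visited by the block-bounded epoch grid.
    """
    rng = _rng(seed)
    fs = config.fs
    n_block = int(round(config.block_len * fs))
    coupling = config.coupling_map()
    amplitudes = dict(config.osc_amplitudes)
    n_ch = len(config.channel_names)
    data = np.zeros((n_ch, int(round(config.session_end * fs))), dtype=np.float32)
    pink_shape = _pink_shape(n_block, fs, config.background_exponent)
    band_shapes = {name: _band_shape(n_block, fs, BANDS[name])
                   for name in amplitudes}

    for bi, (lo, hi) in enumerate(config.block_bounds):
        t_samp = lo + np.arange(n_block) / fs
        lat = np.interp(t_samp, latent_times, latent).astype(np.float32)
        i0 = int(round(lo * fs))
        col = slice(i0, i0 + n_block)
        for ci, ch in enumerate(config.channel_names):
            x = config.background_scale * _shaped_noise(rng, n_block, pink_shape)
            for band_name, amp in amplitudes.items():
                osc = _shaped_noise(rng, n_block, band_shapes[band_name])
                band, gain = coupling.get(ch, (None, 0.0))
                if band == band_name and gain != 0.0:
                    osc = osc * np.float32(10.0) ** (np.float32(0.5 * gain) * lat)
                x = x + np.float32(amp) * osc
            data[ci, col] = x
    return EEGRecording(data, fs, list(config.channel_names), t0=0.0,
                        block_bounds=config.block_bounds)


def simulate_driving(config: SimConfig, latent_times, latent, seed) -> pd.DataFrame:
    """Vehicle log: AR(1) lane wander with latent-dependent innovation scale."""
    rng = _rng(seed)
    fs = config.vehicle_fs
    dt = 1.0 / fs
    phi = np.exp(-dt / config.lane_tau)
    stat_scale = np.sqrt(1 - phi**2)
    frames = []
    for bi, (lo, hi) in enumerate(config.block_bounds):
        n = int(round(config.block_len * fs))
        t = lo + np.arange(n) * dt
        lat = np.interp(t, latent_times, latent)
        scale = config.lane_base_sd * np.maximum(
            1.0 + config.lane_latent_gain * lat, 0.15)
        shocks = rng.standard_normal(n) * stat_scale * scale
        shocks[0] = rng.standard_normal() * scale[0]
        x = signal.lfilter([1.0], [1.0, -phi], shocks)
        frames.append(pd.DataFrame({"t_s": t, "lane_offset_m": x,
                                    "block_id": bi}))
    return pd.concat(frames, ignore_index=True)


def _image_pool(config: SimConfig):
    """Deterministic per-image difficulties shared across participants."""
    rng = np.random.default_rng(config.stimulus_seed)
    pool = {}
    difficulty = {}
    next_id = 0
    for cls, mu in zip(config.target_classes, config.class_difficulty):
        ids = np.arange(next_id, next_id + config.images_per_class)
        next_id += config.images_per_class
        pool[cls] = ids
        for i in ids:
            difficulty[int(i)] = float(mu + config.image_difficulty_sd
                                       * rng.standard_normal())
    return pool, difficulty


def simulate_rsvp(config: SimConfig, latent_times, latent, seed):
    """5 Hz image stream + button presses.

    Returns ``(events, presses, info)`` where ``info`` carries the
    per-block target class/probability and the shared image-difficulty
    table.
    """
    rng = _rng(seed)
    pool, difficulty = _image_pool(config)
    isi = 1.0 / config.rsvp_rate

    classes = list(config.target_classes)
    order = list(rng.permutation(len(classes)))
    # five distinct classes over blocks 1..5; block 6 repeats block 1
    class_by_block = {b: classes[order[b % len(classes)]]
                      for b in range(config.n_blocks)}
    if config.n_blocks >= 2:
        class_by_block[config.n_blocks - 1] = class_by_block[0]
    probs = list(rng.permutation(np.asarray(config.target_probs)))
    prob_by_block = {b: float(probs[b % len(probs)]) for b in range(config.n_blocks)}

    nontarget_id = -100  # non-target filler images (difficulty irrelevant)
    ev_rows, press_rows = [], []
    for b, (lo, hi) in enumerate(config.block_bounds):
        cls = class_by_block[b]
        p_t = prob_by_block[b]
        onsets = np.arange(lo, hi - 1e-9, isi)
        blink = (np.round((onsets - lo) / isi).astype(int)
                 % int(round(config.blink_period / isi)) == 0) & (onsets > lo)
        lat = np.interp(onsets, latent_times, latent)
        for on, is_blink, la in zip(onsets, blink, lat):
            if is_blink:
                ev_rows.append((on, -1, False, b, cls, p_t, True))
                continue
            if rng.random() < p_t:
                img = int(rng.choice(pool[cls]))
                ev_rows.append((on, img, True, b, cls, p_t, False))
                d = difficulty[img]
                p_hit = 1.0 / (1.0 + np.exp(-(config.hit_intercept
                                              - config.hit_latent_slope * la
                                              - config.hit_difficulty_slope * d)))
                if rng.random() < p_hit:
                    rt = (config.rt_base_ms + config.rt_latent_ms * la
                          + config.rt_difficulty_ms * d
                          + config.rt_noise_ms * rng.standard_normal())
                    rt = float(np.clip(rt, 305.0, 995.0))
                    dur = max(30.0, config.duration_base_ms
                              + config.duration_latent_ms * la
                              + config.duration_noise_ms * rng.standard_normal())
                    press_rows.append((on + rt / 1000.0,
                                       on + rt / 1000.0 + dur / 1000.0))
            else:
                ev_rows.append((on, nontarget_id, False, b, cls, p_t, False))
                p_fa = 1.0 / (1.0 + np.exp(-(config.fa_intercept
                                             + config.fa_latent_slope * la)))
                if rng.random() < p_fa:
                    lag = float(np.clip(0.6 + 0.1 * rng.standard_normal(),
                                        0.31, 0.99))
                    dur = max(30.0, config.duration_base_ms
                              + config.duration_noise_ms * rng.standard_normal())
                    press_rows.append((on + lag, on + lag + dur / 1000.0))

    events = pd.DataFrame(ev_rows, columns=["t_onset_s", "image_id", "is_target",
                                            "block_id", "target_class",
                                            "target_prob", "is_blink"])
    presses = pd.DataFrame(sorted(press_rows),
                           columns=["press_on_s", "press_off_s"])
    # drop presses overlapping an earlier press (single button)
    if len(presses):
        keep, last_off = [], -np.inf
        for on, off in presses.itertuples(index=False):
            if on >= last_off:
                keep.append(True)
                last_off = off
            else:
                keep.append(False)
        presses = presses[np.asarray(keep)].reset_index(drop=True)
    info = {"class_by_block": class_by_block, "prob_by_block": prob_by_block,
            "image_difficulty": difficulty}
    return events, presses, info


@dataclass
class SessionBundle:
    """Everything one simulated participant produced."""

    config: SimConfig
    truth: GroundTruth
    eeg: EEGRecording | None = None
    vehicle: pd.DataFrame | None = None
    rsvp_events: pd.DataFrame | None = None
    rsvp_presses: pd.DataFrame | None = None


def simulate_session(config: SimConfig, seed, task: str = "driving",
                     with_eeg: bool = True) -> SessionBundle:
    """Simulate one participant's session for ``task`` in
    {'driving', 'rsvp', 'both'}."""
    if task not in ("driving", "rsvp", "both"):
        raise ParameterError(f"unknown task {task!r}")
    if isinstance(seed, np.random.Generator):
        ss = np.random.SeedSequence(int(seed.integers(2**63)))
    elif isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    latent_seed, eeg_seed, drive_seed, rsvp_seed = [
        np.random.default_rng(s) for s in ss.spawn(4)]
    lt, lx = simulate_latent(config, latent_seed)
    truth = GroundTruth(lt, lx, config.informative_channels,
                        config.coupling_map(), config.block_bounds)
    bundle = SessionBundle(config, truth)
    if with_eeg:
        bundle.eeg = simulate_eeg(config, lt, lx, eeg_seed)
    if task in ("driving", "both"):
        bundle.vehicle = simulate_driving(config, lt, lx, drive_seed)
    if task in ("rsvp", "both"):
        events, presses, info = simulate_rsvp(config, lt, lx, rsvp_seed)
        bundle.rsvp_events = events
        bundle.rsvp_presses = presses
        truth.target_prob_by_block = info["prob_by_block"]
        truth.target_class_by_block = info["class_by_block"]
        truth.image_difficulty = info["image_difficulty"]
    return bundle


def simulate_rsvp_cohort(config: SimConfig, n_participants: int, seed):
    """Behavioral-only RSVP sessions for a cohort sharing the image pool.

    Used to build the per-image grand-average table; EEG is not generated.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_participants):
        rng = np.random.default_rng(child)
        lt, lx = simulate_latent(config, rng)
        events, presses, info = simulate_rsvp(config, lt, lx, rng)
        out.append((events, presses, info))
    return out


def null_config(**overrides) -> SimConfig:
    """A configuration with every latent gain zeroed.

    The alertness state drives neither the EEG band powers nor any
    behavioral parameter, so estimated and actual behavior share nothing;
    used for significance-calibration studies.
    """
    base = SimConfig(coupling=(), lane_latent_gain=0.0, hit_latent_slope=0.0,
                     rt_latent_ms=0.0, duration_latent_ms=0.0,
                     fa_latent_slope=0.0)
    return replace(base, **overrides) if overrides else base
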