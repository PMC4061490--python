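"""EEG preprocessing and moving-window log power spectral density.

The PSD pipeline: sliding 750-point epochs (~3 s at 256 Hz) with a
500-point step; each epoch is subdivided into 125-point Hann windows with a
25-point step (26 windows), each zero-padded to a 256-point FFT; a 5-sample
median filter runs across the window axis at every frequency bin to
suppress transient artifacts; the filtered window spectra are averaged and
converted to log10; the 1-40 Hz bins (1 Hz spacing at fs=256, nfft=256)
are kept.
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .containers import EEGRecording, MontageMap, PSDTimeSeries
from .errors import ConfigurationError, DataError, ParameterError
from .smoothing import DEFAULT_WINDOW_S, smooth_series

#: Floor applied before the log transform so an identically-zero window
#: (e.g. a DC channel after high-pass) cannot produce -inf.
_POWER_FLOOR = 1e-20


def preprocess(raw: EEGRecording, mastoid_labels=("M1", "M2"),
               band=(0.5, 50.0), target_fs: float = 256.0) -> EEGRecording:
    """Mastoid re-reference, anti-aliased down-sampling, zero-phase band-pass.

    The band-pass is a cascade of a 2nd-order Butterworth high-pass at
    ``band[0]`` and an 8th-order elliptic low-pass (0.01 dB ripple, 80 dB
    stopband) at ``band[1]``, both applied forward-backward (zero phase).
    """
    lo, hi = band
    if hi >= target_fs / 2.0:
        raise ParameterError(
            f"band upper edge {hi} Hz must lie below Nyquist ({target_fs / 2} Hz)"
        )
    if not 0 < lo < hi:
        raise ParameterError("band must satisfy 0 < lo < hi")
    missing = [m for m in mastoid_labels if m not in raw.channel_names]
    if missing:
        raise ConfigurationError(f"mastoid labels missing from recording: {missing}")

    data = np.asarray(raw.data, dtype=float)
    mastoid_idx = [raw.channel_index(m) for m in mastoid_labels]
    data = data - data[mastoid_idx].mean(axis=0, keepdims=True)

    if target_fs != raw.fs:
        frac = Fraction(target_fs / raw.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator,
                                    axis=1, padtype="line")

    sos_hp = signal.butter(2, lo, btype="highpass", fs=target_fs, output="sos")
    sos_lp = signal.ellip(8, 0.01, 80.0, hi, btype="lowpass", fs=target_fs, output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    data = signal.sosfiltfilt(sos, data, axis=1)

    return EEGRecording(data, float(target_fs), raw.channel_names,
                        raw.t0, raw.block_bounds)


def downselect_montage(eeg: EEGRecording, montage: list[MontageMap]) -> EEGRecording:
    """Average each montage entry's source electrodes into one output channel."""
    targets = [m.target for m in montage]
    if len(set(targets)) != len(targets):
        raise ConfigurationError("montage target labels must be unique")
    rows = []
    for entry in montage:
        idx = [eeg.channel_index(s) for s in entry.sources]
        rows.append(eeg.data[idx].mean(axis=0))
    return EEGRecording(np.asarray(rows), eeg.fs, targets, eeg.t0, eeg.block_bounds)


def _median5(a, b, c, d, e):
    """Elementwise median of five arrays via a min/max network
    (median3(max(min(a,b), min(c,d)), min(max(a,b), max(c,d)), e))."""
    m = np.maximum(np.minimum(a, b), np.minimum(c, d))
    n = np.minimum(np.maximum(a, b), np.maximum(c, d))
    return np.maximum(np.minimum(m, n), np.minimum(np.maximum(m, n), e))


def _sliding_median(power: np.ndarray, order: int, axis: int = 1) -> np.ndarray:
    """Median filter along ``axis`` (the window axis), edges handled by
    shrinking the window."""
    power = np.moveaxis(power, axis, -1)
    n_w = power.shape[-1]
    half = order // 2
    out = np.empty_like(power)
    if order == 5 and n_w >= 5:
        out[..., 2:n_w - 2] = _median5(*(power[..., k:k + n_w - 4]
                                         for k in range(5)))
    elif n_w >= order:
        view = np.lib.stride_tricks.sliding_window_view(power, order, axis=-1)
        stacked = np.ascontiguousarray(view)
        out[..., half:n_w - half] = np.partition(stacked, half, axis=-1)[..., half]
    for i in range(min(half, n_w)):
        out[..., i] = np.median(power[..., : i + half + 1], axis=-1)
        out[..., n_w - 1 - i] = np.median(power[..., n_w - 1 - i - half:], axis=-1)
    return np.moveaxis(out, -1, axis)


def compute_psd(eeg: EEGRecording, epoch_len: int = 750, epoch_step: int = 500,
                win_len: int = 125, win_step: int = 25, nfft: int = 256,
                median_order: int = 5, fmin: float = 1.0, fmax: float = 40.0,
                _chunk: int = 64) -> PSDTimeSeries:
    """Moving-average log PSD per channel on the sliding epoch grid.

    Epochs never straddle block boundaries when the recording carries
    ``block_bounds``. Power is the magnitude-squared one-sided FFT of the
    Hann-windowed, zero-padded segment (no density scaling); the subsequent
    PCA+regression is invariant to any fixed scaling of power.
    """
    if median_order % 2 == 0 or median_order < 1:
        raise ParameterError("median_order must be odd and positive")
    if win_len > epoch_len or win_step < 1 or epoch_step < 1:
        raise ParameterError("inconsistent epoch/window parameters")

    freqs_all = np.fft.rfftfreq(nfft, d=1.0 / eeg.fs)
    keep = np.flatnonzero((freqs_all >= fmin - 1e-9) & (freqs_all <= fmax + 1e-9))
    if keep.size == 0:
        raise ParameterError("no FFT bins inside the requested frequency range")
    # Computation runs in the recording's own precision (float32 recordings
    # stay float32; anything else is promoted to float64).
    work_dtype = (np.float32 if np.asarray(eeg.data).dtype == np.float32
                  else np.float64)
    window = np.hanning(win_len).astype(work_dtype)
    w_offsets = np.arange(0, epoch_len - win_len + 1, win_step)

    if eeg.block_bounds:
        blocks = []
        for b, (lo, hi) in enumerate(eeg.block_bounds):
            i0 = int(np.ceil((lo - eeg.t0) * eeg.fs - 1e-9))
            i1 = int(np.floor((hi - eeg.t0) * eeg.fs + 1e-9))
            blocks.append((b, i0, min(i1, eeg.n_samples)))
    else:
        blocks = [(0, 0, eeg.n_samples)]

    lp_parts, t_parts, b_parts = [], [], []
    data = np.asarray(eeg.data, dtype=work_dtype)
    for b, i0, i1 in blocks:
        n = i1 - i0
        if n < epoch_len:
            raise DataError(
                f"block {b} has {n} samples, shorter than one epoch ({epoch_len})"
            )
        starts = i0 + np.arange(0, n - epoch_len + 1, epoch_step)
        block_power = np.empty((starts.size, eeg.n_channels, keep.size))
        for c0 in range(0, starts.size, _chunk):
            sl = starts[c0:c0 + _chunk]
            idx = sl[:, None, None] + w_offsets[None, :, None] + np.arange(win_len)[None, None, :]
            seg = data[:, idx]  # (ch, epochs, windows, win_len)
            seg *= window
            spec = sp_fft.rfft(seg, n=nfft, axis=-1)
            power = (spec.real ** 2 + spec.imag ** 2)[..., keep]
            power = _sliding_median(power, median_order, axis=2)
            block_power[c0:c0 + len(sl)] = power.mean(axis=2).transpose(1, 0, 2)
        lp_parts.append(np.log10(np.maximum(block_power, _POWER_FLOOR)))
        t_parts.append(eeg.t0 + (starts + epoch_len / 2.0) / eeg.fs)
        b_parts.append(np.full(starts.size, b, dtype=int))

    return PSDTimeSeries(
        np.concatenate(lp_parts, axis=0),
        freqs_all[keep],
        np.concatenate(t_parts),
        eeg.channel_names,
        np.concatenate(b_parts),
    )


def smooth_psd(psd: PSDTimeSeries, window: float = DEFAULT_WINDOW_S,
               block_bounds=None) -> PSDTimeSeries:
    """Apply the centered block-aware mean filter to every channel/frequency."""
    flat = psd.logpower.reshape(psd.n_epochs, -1)
    sm = smooth_series(psd.epoch_times, flat, window=window,
                       block_ids=psd.block_ids, block_bounds=block_bounds)
    return PSDTimeSeries(sm.reshape(psd.logpower.shape), psd.freqs,
                         psd.epoch_times, psd.channel_names, psd.block_ids)
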