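"""Core in-memory containers for the estimation pipeline.

Time convention: seconds, float64, session-relative (``t0`` = 0 for
simulated sessions). Block bounds are half-open intervals ``[start, end)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, ParameterError

#: BioSemi 32-electrode montage in canonical cap order. This order is the
#: fixed tie-breaking order used by the channel-selection search.
BIOSEMI32 = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

#: Midline montage used by the standard (non-adaptive) modeling scheme.
STANDARD_MONTAGE = ("Fz", "Cz", "Pz", "Oz")

#: Classic EEG band limits in Hz (inclusive of integer bins).
THETA_BAND = (4.0, 7.0)
ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 30.0)


def _as_block_bounds(bounds) -> list[tuple[float, float]] | None:
    if bounds is None:
        return None
    out = [(float(a), float(b)) for a, b in bounds]
    for a, b in out:
        if not b > a:
            raise ParameterError(f"block bound ({a}, {b}) is empty")
    return out


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is a channels-by-samples matrix in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    t0: float = 0.0
    block_bounds: list[tuple[float, float]] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise DataError("EEG data must be channels x samples (2-D)")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        self.block_bounds = _as_block_bounds(self.block_bounds)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown channel label {name!r}") from None


@dataclass
class MontageMap:
    """One down-selected output channel averaged from neighbouring electrodes."""

    target: str
    sources: list[str]

    def __post_init__(self):
        self.sources = list(self.sources)
        if not self.sources:
            raise ConfigurationError(f"montage entry {self.target!r} has no sources")


@dataclass
class PSDTimeSeries:
    """Per-channel log10 power on an epoch time grid.

    ``logpower`` has shape (n_epochs, n_channels, n_freqs); ``freqs`` is the
    1..40 Hz integer bin grid by default. ``block_ids`` assigns each epoch
    to an experimental block.
    """

    logpower: np.ndarray
    freqs: np.ndarray
    epoch_times: np.ndarray
    channel_names: list[str]
    block_ids: np.ndarray | None = None

    def __post_init__(self):
        self.logpower = np.asarray(self.logpower, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.epoch_times = np.asarray(self.epoch_times, dtype=float)
        self.channel_names = list(self.channel_names)
        if self.logpower.ndim != 3:
            raise DataError("logpower must be epochs x channels x freqs")
        n_e, n_c, n_f = self.logpower.shape
        if n_c != len(self.channel_names) or n_f != len(self.freqs):
            raise DataError("logpower shape inconsistent with labels")
        if len(self.epoch_times) != n_e:
            raise DataError("epoch_times length mismatch")
        if np.any(np.diff(self.epoch_times) <= 0):
            raise DataError("epoch_times must be strictly increasing")
        if not np.all(np.isfinite(self.logpower)):
            raise DataError("logpower contains non-finite values")
        if self.block_ids is None:
            self.block_ids = np.zeros(n_e, dtype=int)
        else:
            self.block_ids = np.asarray(self.block_ids, dtype=int)
            if len(self.block_ids) != n_e:
                raise DataError("block_ids length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.logpower.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown channel label {name!r}") from None

    def select_channels(self, names) -> "PSDTimeSeries":
        idx = [self.channel_index(n) for n in names]
        return PSDTimeSeries(
            self.logpower[:, idx, :],
            self.freqs,
            self.epoch_times,
            [self.channel_names[i] for i in idx],
            self.block_ids,
        )


@dataclass
class BehaviorSeries:
    """A smoothed behavioral metric on a time grid alignable to PSD epochs."""

    name: str
    times: np.ndarray
    values: np.ndarray
    block_ids: np.ndarray | None = None
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DataError("times/values shape mismatch")
        if self.times.size == 0:
            raise DataError(f"behavior series {self.name!r} is empty")
        if self.block_ids is None:
            self.block_ids = np.zeros(self.times.size, dtype=int)
        else:
            self.block_ids = np.asarray(self.block_ids, dtype=int)
            if self.block_ids.shape != self.times.shape:
                raise DataError("block_ids shape mismatch")

    def resample_to(self, times, block_ids=None) -> "BehaviorSeries":
        """Nearest-time lookup onto a new grid, never crossing block bounds
        when both grids carry block labels."""
        times = np.asarray(times, dtype=float)
        if block_ids is None:
            idx = _nearest_indices(self.times, times)
            out_blocks = self.block_ids[idx]
        else:
            block_ids = np.asarray(block_ids, dtype=int)
            idx = np.empty(times.size, dtype=int)
            for b in np.unique(block_ids):
                sel = block_ids == b
                src = np.flatnonzero(self.block_ids == b)
                if src.size == 0:
                    raise DataError(f"no behavior samples in block {b}")
                idx[sel] = src[_nearest_indices(self.times[src], times[sel])]
            out_blocks = block_ids
        return BehaviorSeries(self.name, times, self.values[idx], out_blocks, self.units)


def _nearest_indices(src_times: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Index of the nearest source time for each query time (ties -> earlier)."""
    pos = np.searchsorted(src_times, query)
    pos = np.clip(pos, 1, len(src_times) - 1) if len(src_times) > 1 else np.zeros_like(pos)
    left = np.clip(pos - 1, 0, len(src_times) - 1)
    right = np.clip(pos, 0, len(src_times) - 1)
    choose_right = (src_times[right] - query) < (query - src_times[left])
    return np.where(choose_right, right, left)
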