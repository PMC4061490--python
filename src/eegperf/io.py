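"""Readers and writers for the pipeline's on-disk artifacts.

Array containers (EEG, PSD, model bundles) are NumPy ``.npz`` archives
with all metadata embedded; tables (events, presses, vehicle logs,
behavior series) are plain CSV with documented headers; reports are JSON.
Times are seconds, session-relative.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BehaviorSeries, EEGRecording, PSDTimeSeries
from .errors import DataError
from .regression import EigenBasis, SpectralRegressionModel

REQUIRED_COLUMNS = {
    "events": ["t_onset_s", "image_id", "is_target", "block_id"],
    "presses": ["press_on_s", "press_off_s"],
    "vehicle": ["t_s", "lane_offset_m", "block_id"],
    "behavior": ["t_s", "value", "block_id"],
}


def _check_columns(df: pd.DataFrame, kind: str, path) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: {kind} table lacks column(s) {missing}; "
                        f"found {list(df.columns)}")
    return df


def read_table(path, kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: malformed CSV ({exc})") from exc
    return _check_columns(df, kind, path)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def save_recording(eeg: EEGRecording, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, data=eeg.data, fs=eeg.fs, channel_names=np.asarray(eeg.channel_names),
        t0=eeg.t0,
        block_bounds=(np.asarray(eeg.block_bounds)
                      if eeg.block_bounds is not None else np.zeros((0, 2))))


def load_recording(path) -> EEGRecording:
    with np.load(path, allow_pickle=False) as z:
        bounds = z["block_bounds"]
        return EEGRecording(
            z["data"], float(z["fs"]), [str(c) for c in z["channel_names"]],
            float(z["t0"]),
            [tuple(b) for b in bounds] if bounds.size else None)


def save_psd(psd: PSDTimeSeries, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, logpower=psd.logpower, freqs=psd.freqs,
                        epoch_times=psd.epoch_times,
                        channel_names=np.asarray(psd.channel_names),
                        block_ids=psd.block_ids)


def load_psd(path) -> PSDTimeSeries:
    with np.load(path, allow_pickle=False) as z:
        return PSDTimeSeries(z["logpower"], z["freqs"], z["epoch_times"],
                             [str(c) for c in z["channel_names"]],
                             z["block_ids"])


def save_behavior(series: BehaviorSeries, path) -> None:
    df = pd.DataFrame({"t_s": series.times, "value": series.values,
                       "block_id": series.block_ids,
                       "metric": series.name, "units": series.units})
    write_table(df, path)


def load_behavior(path) -> BehaviorSeries:
    df = read_table(path, "behavior")
    name = str(df["metric"].iloc[0]) if "metric" in df else "behavior"
    units = str(df["units"].iloc[0]) if "units" in df else ""
    if units == "nan":
        units = ""
    return BehaviorSeries(name, df["t_s"].to_numpy(), df["value"].to_numpy(),
                          df["block_id"].to_numpy(dtype=int), units)


def save_model(model: SpectralRegressionModel, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, V=model.basis.V, eigenvalues=model.basis.eigenvalues,
        means=model.basis.means, total_variance=model.basis.total_variance,
        variance_threshold=model.basis.variance_threshold,
        beta=model.beta, intercept=model.intercept,
        channels=np.asarray(model.channels), metric=np.asarray(model.metric))


def load_model(path) -> SpectralRegressionModel:
    with np.load(path, allow_pickle=False) as z:
        basis = EigenBasis(z["V"], z["eigenvalues"], z["means"],
                           float(z["total_variance"]),
                           float(z["variance_threshold"]))
        return SpectralRegressionModel(basis, z["beta"], float(z["intercept"]),
                                       [str(c) for c in z["channels"]],
                                       str(z["metric"]))


def save_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def read_edf(path, t0: float = 0.0, block_bounds=None) -> EEGRecording:
    """Import an EDF/BDF recording (requires the optional ``mne`` package)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF import requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                        t0=t0, block_bounds=block_bounds)
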