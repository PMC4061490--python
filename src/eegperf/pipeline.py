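"""End-to-end orchestration: simulate/load -> PSD -> behavior -> CV ->
significance -> spectral weights, with a machine-readable report."""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import behavior as bh
from .containers import BehaviorSeries, EEGRecording, PSDTimeSeries
from .errors import ParameterError
from .evaluation import CVResult, loo_block_cv
from .smoothing import DEFAULT_WINDOW_S
from .spectra import compute_psd, smooth_psd
from .weights import aggregate_and_test, relative_weights


@dataclass
class RunConfig:
    """Tunable parameters of one pipeline run; every numeric default is
    overridable and recorded in the run report."""

    scheme: str = "adaptive"
    metric: str = "lane_dev"
    smoothing_window: float = DEFAULT_WINDOW_S
    epoch_len: int = 750
    epoch_step: int = 500
    win_len: int = 125
    win_step: int = 25
    nfft: int = 256
    median_order: int = 5
    variance_threshold: float = 0.01
    k_max: int = 12
    max_iter: int = 500
    sffs_protocol: str = "inner-cv"
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0


def eeg_to_features(eeg: EEGRecording, config: RunConfig) -> PSDTimeSeries:
    """PSD estimation followed by the 90 s block-aware smoother."""
    psd = compute_psd(eeg, epoch_len=config.epoch_len,
                      epoch_step=config.epoch_step, win_len=config.win_len,
                      win_step=config.win_step, nfft=config.nfft,
                      median_order=config.median_order)
    return smooth_psd(psd, window=config.smoothing_window,
                      block_bounds=eeg.block_bounds)


def run_driving_pipeline(eeg: EEGRecording, vehicle, config: RunConfig,
                         psd: PSDTimeSeries | None = None) -> tuple[CVResult, dict]:
    """Full driving analysis; returns the CV result and a report dict."""
    if psd is None:
        psd = eeg_to_features(eeg, config)
    series = bh.lane_deviation_series(vehicle, window=config.smoothing_window,
                                      block_bounds=eeg.block_bounds,
                                      epoch_times=psd.epoch_times,
                                      epoch_blocks=psd.block_ids)
    cv = loo_block_cv(psd, series, scheme=config.scheme,
                      variance_threshold=config.variance_threshold,
                      k_max=config.k_max, max_iter=config.max_iter,
                      protocol=config.sffs_protocol, n_perm=config.n_perm,
                      alpha=config.alpha, seed=config.seed,
                      smoothing_window=config.smoothing_window)
    return cv, summarize_cv(cv, config)


def rsvp_behavior_series(events, presses, metric: str, config: RunConfig,
                         block_bounds, grand_average=None,
                         epoch_times=None, epoch_blocks=None) -> BehaviorSeries:
    """Trial extraction, optional normalization/adjustment, 90 s smoothing."""
    responses = bh.assign_presses(events, presses)
    trials = bh.trial_values(responses, metric)
    if grand_average is not None:
        trials = bh.normalize_behavior(trials, grand_average, metric)
    if metric in ("rt", "duration") and "target_prob" in events.columns:
        prob_by_block = (events.drop_duplicates("block_id")
                         .set_index("block_id")["target_prob"].to_dict())
        trials = bh.adjust_for_probability(trials, metric, prob_by_block)
    return bh.rsvp_metric_series(responses, metric,
                                 window=config.smoothing_window,
                                 block_bounds=block_bounds,
                                 epoch_times=epoch_times,
                                 epoch_blocks=epoch_blocks,
                                 trial_table=trials)


def run_rsvp_pipeline(eeg: EEGRecording, events, presses, metric: str,
                      config: RunConfig, grand_average=None,
                      psd: PSDTimeSeries | None = None) -> tuple[CVResult, dict]:
    if metric not in ("accuracy", "rt", "duration"):
        raise ParameterError(f"unknown RSVP metric {metric!r}")
    if psd is None:
        psd = eeg_to_features(eeg, config)
    series = rsvp_behavior_series(events, presses, metric, config,
                                  eeg.block_bounds, grand_average,
                                  psd.epoch_times, psd.block_ids)
    if len(series.values) != psd.n_epochs:
        # metric unavailable in some block (e.g. no hits): restrict epochs
        keep = np.isin(psd.block_ids, np.unique(series.block_ids))
        psd = PSDTimeSeries(psd.logpower[keep], psd.freqs,
                            psd.epoch_times[keep], psd.channel_names,
                            psd.block_ids[keep])
    cv = loo_block_cv(psd, series, scheme=config.scheme,
                      variance_threshold=config.variance_threshold,
                      k_max=config.k_max, max_iter=config.max_iter,
                      protocol=config.sffs_protocol, n_perm=config.n_perm,
                      alpha=config.alpha, seed=config.seed,
                      smoothing_window=config.smoothing_window)
    return cv, summarize_cv(cv, config)


def summarize_cv(cv: CVResult, config: RunConfig) -> dict:
    """JSON-ready report of one cross-validated estimate."""
    profiles = [relative_weights(m) for m in cv.models]
    summary = aggregate_and_test(profiles, alpha=config.alpha)
    report = {
        "scheme": cv.scheme,
        "metric": cv.metric,
        "overall_R": cv.overall_r,
        "per_block_R": cv.fold_r,
        "nRMSE": cv.nrmse,
        "p": cv.p,
        "threshold": cv.threshold,
        "significant": cv.significant,
        "n_perm": config.n_perm,
        "seed": config.seed,
        "n_epochs": int(cv.y.size),
        "config": asdict(config),
        "spectral_weights": {
            "freqs_hz": summary.freqs,
            "mean_profile": summary.mean_profile,
            "significant": summary.significant,
        },
    }
    if cv.scheme == "adaptive":
        report["selected_channels_per_fold"] = [list(s.best_subset)
                                                for s in cv.sffs_results]
        report["mean_channels_selected"] = float(np.mean(
            [len(s.best_subset) for s in cv.sffs_results]))
        report["representative_subset"] = list(cv.representative_subset)
    return report
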