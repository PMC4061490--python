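"""Behavioral target series for the driving and RSVP tasks.

Driving performance is the absolute lane deviation (lateral distance from
the lane center), smoothed per block with the 90 s mean filter. RSVP
performance is derived from button presses assigned to the 5 Hz image
stream: for each press, images with onset 300-1000 ms before the press are
inspected; the oldest target in that window claims the press (reaction
time measured from that target's onset), otherwise the press is a false
alarm assigned to the non-target image nearest to 600 ms before the press.
Per-trial accuracy / RT / press duration are normalized against per-image
grand averages (re-anchored at nominal values 1 / 600 ms / 300 ms) to
remove perceptual-difficulty effects, and RT/duration are additionally
adjusted for the per-block target probability.

Event-table conventions (CSV-compatible):
    events:  t_onset_s, image_id, is_target, block_id [, target_class,
             target_prob, is_blink]
    presses: press_on_s, press_off_s
    vehicle: t_s, lane_offset_m, block_id
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BehaviorSeries
from .errors import ConfigurationError, DataError, ParameterError
from .smoothing import DEFAULT_WINDOW_S, smooth_series

#: Assignment window: images 300-1000 ms before a press are candidates.
RT_WINDOW_S = (0.3, 1.0)
#: A false-alarm press is pinned to the non-target ~600 ms earlier.
FALSE_ALARM_OFFSET_S = 0.6

#: Nominal re-anchoring values for the normalized metrics.
NOMINALS = {"accuracy": 1.0, "rt": 600.0, "duration": 300.0}

#: Default probability-effect slopes in ms per unit target probability.
PROBABILITY_SLOPES = {"rt": -262.0, "duration": -277.0}
REFERENCE_PROBABILITY = 0.06  # mean of the block probabilities 0.01..0.11

METRIC_UNITS = {"lane_dev": "m", "accuracy": "", "rt": "ms", "duration": "ms"}


@dataclass
class ResponseTable:
    """Press-to-image assignments plus per-target hit bookkeeping.

    ``presses`` columns: press_on_s, press_off_s, duration_ms, image_id,
        assigned_to_target, rt_ms (NaN unless target-assigned), block_id,
        unassigned.
    ``targets`` columns: image_id, t_onset_s, block_id, hit, rt_ms,
        duration_ms (NaN on misses).
    """

    presses: pd.DataFrame
    targets: pd.DataFrame

    @property
    def n_hits(self) -> int:
        return int(self.targets["hit"].sum())

    @property
    def n_misses(self) -> int:
        return int((~self.targets["hit"].astype(bool)).sum())

    @property
    def n_false_alarms(self) -> int:
        assigned = self.presses[~self.presses["unassigned"]]
        return int((~assigned["assigned_to_target"].astype(bool)).sum())


def lane_deviation_series(vehicle: pd.DataFrame, window: float = DEFAULT_WINDOW_S,
                          block_bounds=None, epoch_times=None,
                          epoch_blocks=None) -> BehaviorSeries:
    """Absolute lane deviation, smoothed per block; optionally resampled to
    a PSD epoch grid by nearest-time lookup."""
    if len(vehicle) == 0:
        raise DataError("vehicle log is empty")
    t = vehicle["t_s"].to_numpy(dtype=float)
    dev = np.abs(vehicle["lane_offset_m"].to_numpy(dtype=float))
    blocks = (vehicle["block_id"].to_numpy(dtype=int)
              if "block_id" in vehicle else np.zeros(len(vehicle), dtype=int))
    sm = smooth_series(t, dev, window=window, block_ids=blocks,
                       block_bounds=block_bounds)
    series = BehaviorSeries("lane_dev", t, sm, blocks, units="m")
    if epoch_times is not None:
        series = series.resample_to(epoch_times, epoch_blocks)
    return series


def assign_presses(events: pd.DataFrame, presses: pd.DataFrame,
                   rt_window: tuple[float, float] = RT_WINDOW_S,
                   fa_offset: float = FALSE_ALARM_OFFSET_S) -> ResponseTable:
    """Assign each button press to exactly one image.

    Window boundaries are inclusive. When several presses could claim the
    same target, the earlier press wins and later presses fall through to
    the false-alarm rule. Presses occurring before any image plus the
    minimum latency remain unassigned (flagged, not dropped).
    """
    ev = events.loc[~events.get("is_blink", pd.Series(False, index=events.index))
                    .astype(bool)].reset_index(drop=True)
    ev = ev.sort_values("t_onset_s").reset_index(drop=True)
    onsets = ev["t_onset_s"].to_numpy(dtype=float)
    is_target = ev["is_target"].to_numpy(dtype=bool)
    blocks = (ev["block_id"].to_numpy(dtype=int)
              if "block_id" in ev else np.zeros(len(ev), dtype=int))
    target_rows = np.flatnonzero(is_target)
    nt_rows = np.flatnonzero(~is_target)
    lo, hi = rt_window

    pr = presses.sort_values("press_on_s").reset_index(drop=True)
    p_on = pr["press_on_s"].to_numpy(dtype=float)
    p_off = pr["press_off_s"].to_numpy(dtype=float)
    if np.any(p_off <= p_on):
        raise DataError("press offsets must follow onsets")

    claimed = np.zeros(len(ev), dtype=bool)
    rt_by_row = np.full(len(ev), np.nan)
    dur_by_row = np.full(len(ev), np.nan)
    rec = {k: [] for k in ("image_id", "assigned_to_target", "rt_ms",
                           "block_id", "unassigned")}
    for on, off in zip(p_on, p_off):
        w_lo, w_hi = on - hi, on - lo  # inclusive candidate onset range
        cand = target_rows[(onsets[target_rows] >= w_lo - 1e-12)
                           & (onsets[target_rows] <= w_hi + 1e-12)]
        cand = cand[~claimed[cand]]
        if cand.size:
            row = cand[0]  # oldest target in the window
            claimed[row] = True
            rt_by_row[row] = (on - onsets[row]) * 1000.0
            dur_by_row[row] = (off - on) * 1000.0
            rec["image_id"].append(ev.at[row, "image_id"])
            rec["assigned_to_target"].append(True)
            rec["rt_ms"].append((on - onsets[row]) * 1000.0)
            rec["block_id"].append(blocks[row])
            rec["unassigned"].append(False)
            continue
        # false alarm: non-target nearest to (press - fa_offset)
        anchor = on - fa_offset
        elig = nt_rows[onsets[nt_rows] <= on - lo + 1e-12]
        if elig.size == 0:
            warnings.warn(f"press at t={on:.3f}s precedes the image stream; "
                          "left unassigned", RuntimeWarning, stacklevel=2)
            rec["image_id"].append(-1)
            rec["assigned_to_target"].append(False)
            rec["rt_ms"].append(np.nan)
            rec["block_id"].append(-1)
            rec["unassigned"].append(True)
            continue
        row = elig[np.argmin(np.abs(onsets[elig] - anchor))]
        rec["image_id"].append(ev.at[row, "image_id"])
        rec["assigned_to_target"].append(False)
        rec["rt_ms"].append(np.nan)
        rec["block_id"].append(blocks[row])
        rec["unassigned"].append(False)

    press_table = pd.DataFrame({
        "press_on_s": p_on,
        "press_off_s": p_off,
        "duration_ms": (p_off - p_on) * 1000.0,
        **rec,
    })

    tgt = ev.loc[target_rows, ["image_id", "t_onset_s"]].reset_index(drop=True)
    tgt["block_id"] = blocks[target_rows]
    tgt["hit"] = claimed[target_rows]
    tgt["rt_ms"] = rt_by_row[target_rows]
    tgt["duration_ms"] = dur_by_row[target_rows]
    return ResponseTable(press_table, tgt)


def trial_values(responses: ResponseTable, metric: str) -> pd.DataFrame:
    """Per-trial metric values at target-image onset times.

    accuracy: every target contributes hit (1) or miss (0);
    rt / duration: hits only, in milliseconds.
    """
    if metric not in ("accuracy", "rt", "duration"):
        raise ParameterError(f"unknown RSVP metric {metric!r}")
    tgt = responses.targets
    if metric == "accuracy":
        df = tgt[["image_id", "t_onset_s", "block_id"]].copy()
        df["value"] = tgt["hit"].astype(float)
    else:
        col = "rt_ms" if metric == "rt" else "duration_ms"
        hits = tgt[tgt["hit"].astype(bool)]
        df = hits[["image_id", "t_onset_s", "block_id"]].copy()
        df["value"] = hits[col].to_numpy(dtype=float)
    return df.reset_index(drop=True)


def rsvp_metric_series(responses: ResponseTable, metric: str,
                       window: float = DEFAULT_WINDOW_S, block_bounds=None,
                       epoch_times=None, epoch_blocks=None,
                       trial_table: pd.DataFrame | None = None) -> BehaviorSeries:
    """Smoothed trial-level metric on the target-onset time grid.

    ``trial_table`` lets callers pass normalized/adjusted trial values
    (from :func:`normalize_behavior` / :func:`adjust_for_probability`);
    by default the raw trial values are used. Blocks without any target
    trial are skipped with a warning.
    """
    df = trial_table if trial_table is not None else trial_values(responses, metric)
    if len(df) == 0:
        raise DataError(f"no trials available for metric {metric!r}")
    df = df.sort_values("t_onset_s")
    t = df["t_onset_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    b = df["block_id"].to_numpy(dtype=int)
    sm = smooth_series(t, v, window=window, block_ids=b,
                       block_bounds=block_bounds)
    series = BehaviorSeries(metric, t, sm, b, units=METRIC_UNITS.get(metric, ""))
    if epoch_times is not None:
        present = set(np.unique(b))
        wanted = (set(np.unique(epoch_blocks)) if epoch_blocks is not None
                  else present)
        missing = wanted - present
        if missing:
            warnings.warn(f"blocks {sorted(missing)} contain no {metric} trials",
                          RuntimeWarning, stacklevel=2)
            if epoch_blocks is not None:
                keep = np.isin(epoch_blocks, sorted(present))
                epoch_times = np.asarray(epoch_times)[keep]
                epoch_blocks = np.asarray(epoch_blocks)[keep]
        series = series.resample_to(epoch_times, epoch_blocks)
    return series


def grand_average_table(response_tables) -> pd.DataFrame:
    """Per-target-image mean accuracy, RT, and duration across participants."""
    frames = []
    for i, rt in enumerate(response_tables):
        tgt = rt.targets.copy()
        tgt["participant"] = i
        frames.append(tgt)
    if not frames:
        raise DataError("need at least one response table")
    pooled = pd.concat(frames, ignore_index=True)
    ga = pooled.groupby("image_id").agg(
        accuracy=("hit", "mean"),
        rt=("rt_ms", "mean"),
        duration=("duration_ms", "mean"),
        n=("hit", "size"),
    ).reset_index()
    return ga


def normalize_behavior(trials: pd.DataFrame, grand_average: pd.DataFrame,
                       metric: str, nominal: float | None = None) -> pd.DataFrame:
    """Per-image grand-average normalization re-anchored at the nominal value.

    normalized = nominal + (response - grand_average[image]).
    """
    if metric not in NOMINALS:
        raise ParameterError(f"unknown metric {metric!r}")
    nominal = NOMINALS[metric] if nominal is None else float(nominal)
    ga = grand_average.set_index("image_id")[metric]
    missing = set(trials["image_id"]) - set(ga.index)
    if missing:
        raise ConfigurationError(
            f"grand-average table lacks image(s): {sorted(missing)[:5]}...")
    out = trials.copy()
    out["value"] = nominal + (trials["value"].to_numpy(dtype=float)
                              - ga.loc[trials["image_id"]].to_numpy(dtype=float))
    return out


def adjust_for_probability(trials: pd.DataFrame, metric: str,
                           block_probability, slope: float | None = None,
                           reference_probability: float = REFERENCE_PROBABILITY) -> pd.DataFrame:
    """Remove the fitted linear target-probability effect from RT/duration.

    ``block_probability`` maps block_id -> target probability (or is a
    scalar). The fitted cross-participant slope (ms per unit probability)
    is subtracted around the reference probability:
    adjusted = value - slope * (p_block - reference). Accuracy is never
    adjusted (use the identity for it).
    """
    if metric not in ("rt", "duration"):
        raise ParameterError("probability adjustment applies to rt/duration only")
    slope = PROBABILITY_SLOPES[metric] if slope is None else float(slope)
    out = trials.copy()
    if np.isscalar(block_probability):
        p = np.full(len(trials), float(block_probability))
    else:
        mapping = dict(block_probability)
        p = np.asarray([mapping[b] for b in trials["block_id"]], dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ParameterError("target probabilities must lie in (0, 1)")
    out["value"] = (trials["value"].to_numpy(dtype=float)
                    - slope * (p - reference_probability))
    return out


def block_linear_trend(series: BehaviorSeries, alpha: float = 0.05) -> pd.DataFrame:
    """Per-block OLS slope of the metric against time, with slope t-test.

    Reporting aid (used to count within-block performance decrements);
    not part of the estimation path.
    """
    rows = []
    for b in np.unique(series.block_ids):
        sel = series.block_ids == b
        t, v = series.times[sel], series.values[sel]
        if t.size < 3 or np.ptp(t) == 0:
            continue
        res = stats.linregress(t, v)
        rows.append({"block_id": int(b), "slope": res.slope,
                     "p_value": res.pvalue,
                     "significant": bool(res.pvalue < alpha)})
    return pd.DataFrame(rows)
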