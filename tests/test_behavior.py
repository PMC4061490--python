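"""Button-press assignment, normalization, and behavioral series."""
import numpy as np
import pandas as pd
import pytest

from eegperf import (BehaviorSeries, adjust_for_probability, assign_presses,
                     block_linear_trend, grand_average_table,
                     lane_deviation_series, normalize_behavior,
                     rsvp_metric_series, trial_values)
from eegperf.errors import ConfigurationError, ParameterError


def events_frame(onsets, targets, block=0):
    return pd.DataFrame({
        "t_onset_s": onsets,
        "image_id": np.arange(len(onsets)),
        "is_target": targets,
        "block_id": block,
    })


def presses_frame(times, dur=0.3):
    times = np.asarray(times, dtype=float)
    return pd.DataFrame({"press_on_s": times, "press_off_s": times + dur})


def rsvp_stream(n=100, target_every=None, block=0, t0=0.0):
    onsets = t0 + np.arange(n) * 0.2
    targets = np.zeros(n, dtype=bool)
    if target_every:
        targets[::target_every] = True
    return events_frame(onsets, targets, block)


# ------------------------------------------------------------ lane deviation
class TestLaneDeviation:
    def _vehicle(self, offsets, fs=100.0):
        n = len(offsets)
        return pd.DataFrame({"t_s": np.arange(n) / fs,
                             "lane_offset_m": offsets, "block_id": 0})

    def test_constant_offset_gives_absolute_value(self):
        s = lane_deviation_series(self._vehicle(np.full(20000, -0.5)))
        assert np.allclose(s.values, 0.5)
        assert s.units == "m"

    def test_centered_driving_gives_zero(self):
        s = lane_deviation_series(self._vehicle(np.zeros(20000)))
        assert np.allclose(s.values, 0.0)

    def test_square_wave_smooths_to_one(self):
        offsets = np.where(np.arange(20000) % 200 < 100, 1.0, -1.0)
        s = lane_deviation_series(self._vehicle(offsets))
        assert np.allclose(s.values, 1.0)


# ------------------------------------------------------------ press matching
class TestAssignPresses:
    def test_lone_target_hit_rt_500(self):
        ev = events_frame([0.0, 0.2, 0.4], [True, False, False])
        resp = assign_presses(ev, presses_frame([0.5]))
        assert resp.n_hits == 1 and resp.n_false_alarms == 0
        assert resp.presses["rt_ms"].iloc[0] == pytest.approx(500.0)

    def test_oldest_target_claims_the_press(self):
        ev = events_frame([0.0, 0.5], [True, True])
        resp = assign_presses(ev, presses_frame([0.9]))
        assert resp.presses["image_id"].iloc[0] == 0
        assert resp.presses["rt_ms"].iloc[0] == pytest.approx(900.0)
        assert resp.n_misses == 1  # the newer target stays unclaimed

    def test_false_alarm_assigned_600ms_back(self):
        ev = rsvp_stream(n=60)  # all non-targets, onsets every 200 ms
        resp = assign_presses(ev, presses_frame([10.0]))
        row = resp.presses.iloc[0]
        assert not row["assigned_to_target"] and not row["unassigned"]
        onset = ev.loc[ev["image_id"] == row["image_id"], "t_onset_s"].iloc[0]
        assert onset == pytest.approx(9.4)  # nearest onset to press - 600 ms
        assert np.isnan(row["rt_ms"])

    def test_press_before_stream_is_unassigned(self):
        ev = events_frame([1.0], [True])
        with pytest.warns(RuntimeWarning, match="unassigned"):
            resp = assign_presses(ev, presses_frame([0.2]))
        assert resp.presses["unassigned"].iloc[0]

    def test_earlier_press_claims_shared_target(self):
        ev = events_frame([0.0, 0.2, 0.4, 0.6], [True, False, False, False])
        resp = assign_presses(ev, presses_frame([0.5, 0.8]))
        assert resp.presses["assigned_to_target"].tolist() == [True, False]
        assert resp.n_false_alarms == 1

    def test_window_boundaries_inclusive(self):
        ev = events_frame([0.0], [True])
        assert assign_presses(ev, presses_frame([0.3])).n_hits == 1
        assert assign_presses(ev, presses_frame([1.0])).n_hits == 1

    def test_hits_plus_misses_equals_targets(self):
        rng = np.random.default_rng(0)
        ev = rsvp_stream(n=400, target_every=13)
        hit_targets = ev.loc[ev["is_target"], "t_onset_s"].to_numpy()
        press_t = hit_targets[rng.random(hit_targets.size) < 0.7] + 0.5
        resp = assign_presses(ev, presses_frame(np.sort(press_t)))
        n_targets = int(ev["is_target"].sum())
        assert resp.n_hits + resp.n_misses == n_targets
        assert resp.n_false_alarms <= len(press_t)

    def test_order_independent_over_presses(self):
        ev = rsvp_stream(n=200, target_every=11)
        times = [3.7, 8.05, 1.1, 15.0]
        a = assign_presses(ev, presses_frame(times))
        b = assign_presses(ev, presses_frame(sorted(times)))
        pd.testing.assert_frame_equal(
            a.presses.sort_values("press_on_s").reset_index(drop=True),
            b.presses.sort_values("press_on_s").reset_index(drop=True))


# ------------------------------------------------------------- metric series
class TestMetricSeries:
    def _responses(self, rts):
        ev = events_frame(np.arange(len(rts)) * 10.0, [True] * len(rts))
        times = [o + rt for o, rt in zip(np.arange(len(rts)) * 10.0, rts)
                 if rt is not None]
        return assign_presses(ev, presses_frame(times))

    def test_all_hits_accuracy_one(self):
        resp = self._responses([0.5, 0.5, 0.5])
        s = rsvp_metric_series(resp, "accuracy")
        assert np.allclose(s.values, 1.0)

    def test_alternating_hits_interior_half(self):
        resp = self._responses([0.5, None] * 10)
        s = rsvp_metric_series(resp, "accuracy", window=60.0)
        interior = (s.times >= 30) & (s.times <= s.times[-1] - 30)
        assert np.allclose(s.values[interior], 0.5, atol=0.1)

    def test_rt_mean_of_window(self):
        resp = self._responses([0.4, 0.6, 0.8])
        s = rsvp_metric_series(resp, "rt", window=1000.0)
        assert np.allclose(s.values, 600.0)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ParameterError):
            trial_values(self._responses([0.5]), "speed")


# -------------------------------------------------------------- normalization
class TestNormalization:
    def _ga(self, rows):
        return pd.DataFrame(rows)

    def test_nominal_anchoring_examples(self):
        ga = self._ga([{"image_id": 1, "accuracy": 0.8, "rt": 650.0,
                        "duration": 320.0}])
        acc = pd.DataFrame({"image_id": [1], "value": [1.0]})
        assert normalize_behavior(acc, ga, "accuracy")["value"].iloc[0] == pytest.approx(1.2)
        rt = pd.DataFrame({"image_id": [1], "value": [700.0]})
        assert normalize_behavior(rt, ga, "rt")["value"].iloc[0] == pytest.approx(650.0)
        dur = pd.DataFrame({"image_id": [1], "value": [250.0]})
        assert normalize_behavior(dur, ga, "duration")["value"].iloc[0] == pytest.approx(230.0)

    def test_missing_image_raises(self):
        ga = self._ga([{"image_id": 1, "accuracy": 0.8, "rt": 1.0, "duration": 1.0}])
        trials = pd.DataFrame({"image_id": [2], "value": [1.0]})
        with pytest.raises(ConfigurationError):
            normalize_behavior(trials, ga, "accuracy")

    def test_preserves_differences_between_responses(self):
        ga = self._ga([{"image_id": 5, "accuracy": 0.6, "rt": 500.0,
                        "duration": 300.0}])
        trials = pd.DataFrame({"image_id": [5, 5], "value": [420.0, 470.0]})
        out = normalize_behavior(trials, ga, "rt")
        assert np.diff(out["value"])[0] == pytest.approx(50.0)


class TestProbabilityAdjustment:
    def test_reference_probability_unchanged(self):
        trials = pd.DataFrame({"block_id": [0], "value": [600.0]})
        out = adjust_for_probability(trials, "rt", {0: 0.06})
        assert out["value"].iloc[0] == pytest.approx(600.0)

    def test_high_probability_block_shifted(self):
        trials = pd.DataFrame({"block_id": [0], "value": [600.0]})
        out = adjust_for_probability(trials, "rt", {0: 0.11})
        assert out["value"].iloc[0] == pytest.approx(613.1)

    def test_zero_slope_is_identity(self):
        trials = pd.DataFrame({"block_id": [0], "value": [500.0]})
        out = adjust_for_probability(trials, "duration", {0: 0.11}, slope=0.0)
        assert out["value"].iloc[0] == pytest.approx(500.0)

    def test_invalid_probability_rejected(self):
        trials = pd.DataFrame({"block_id": [0], "value": [1.0]})
        with pytest.raises(ParameterError):
            adjust_for_probability(trials, "rt", {0: 1.5})
        with pytest.raises(ParameterError):
            adjust_for_probability(trials, "accuracy", {0: 0.05})


def test_grand_average_across_participants():
    ev = events_frame([0.0, 10.0], [True, True])
    p1 = assign_presses(ev, presses_frame([0.5, 10.5]))      # hits both
    p2 = assign_presses(ev, presses_frame([0.7]))            # hits first only
    ga = grand_average_table([p1, p2])
    row0 = ga[ga["image_id"] == 0].iloc[0]
    assert row0["accuracy"] == pytest.approx(1.0)
    assert row0["rt"] == pytest.approx(600.0)  # mean of 500 and 700
    row1 = ga[ga["image_id"] == 1].iloc[0]
    assert row1["accuracy"] == pytest.approx(0.5)


def test_block_linear_trend_detects_decrement():
    rng = np.random.default_rng(0)
    t = np.arange(300.0)
    v = 0.01 * t + 0.05 * rng.standard_normal(300)
    series = BehaviorSeries("accuracy", t, v)
    trend = block_linear_trend(series)
    assert trend["significant"].iloc[0]
    assert trend["slope"].iloc[0] == pytest.approx(0.01, rel=0.2)
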