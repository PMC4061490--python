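"""Build the normalized RSVP behavioral targets from raw event streams.

Button presses are assigned to images (oldest target 300-1000 ms before
the press; otherwise the non-target ~600 ms back counts as a false
alarm). Accuracy / reaction time / press duration are then normalized by
per-image grand averages (nominals 1, 600 ms, 300 ms) to remove
perceptual difficulty, RT and duration are adjusted for each block's
target probability, and everything is smoothed with the centered 90 s
mean filter.
"""
from dataclasses import replace

import eegperf as ep

cfg = replace(ep.SimConfig(), n_blocks=3, block_len=300.0)
bundle = ep.simulate_session(cfg, seed=5, task="rsvp")

responses = ep.assign_presses(bundle.rsvp_events, bundle.rsvp_presses)
print(f"targets: {responses.n_hits} hits, {responses.n_misses} misses, "
      f"{responses.n_false_alarms} false alarms")

# grand average over a small cohort sharing the image pool (plus self)
cohort = ep.simulate_rsvp_cohort(cfg, 5, seed=99)
ga = ep.grand_average_table(
    [ep.assign_presses(e, p) for e, p, _ in cohort] + [responses])

rc = ep.RunConfig(metric="rt")
for metric in ("accuracy", "rt", "duration"):
    series = ep.rsvp_behavior_series(bundle.rsvp_events, bundle.rsvp_presses,
                                     metric, rc, cfg.block_bounds,
                                     grand_average=ga)
    unit = f" {series.units}" if series.units else ""
    print(f"{metric:>9}: {series.values.size} smoothed samples, "
          f"mean {series.values.mean():.3f}{unit} "
          f"(nominal {ep.behavior.NOMINALS[metric]:g})")
print("values above the nominal mean the participant did worse/slower than")
print("the cohort average on those particular images")
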