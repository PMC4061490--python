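"""Apply driving-task models to RSVP behavior (and note the sign flip).

One participant's latent alertness drives both tasks, so models fit on
lane deviation carry over to RSVP accuracy. A slope+offset least-squares
rescale maps the estimate onto the new metric's units; it cannot change
the correlation magnitude, and the sign is reported unrescaled — lane
deviation worsens (rises) while accuracy worsens (falls), so a *negative*
cross-task R is the expected signature of shared state.
"""
from dataclasses import replace

import eegperf as ep

cfg = replace(ep.SimConfig(), n_blocks=3, block_len=300.0)
bundle = ep.simulate_session(cfg, seed=13, task="both")
psd = ep.smooth_psd(ep.compute_psd(bundle.eeg), block_bounds=cfg.block_bounds)

lane = ep.lane_deviation_series(bundle.vehicle, block_bounds=cfg.block_bounds,
                                epoch_times=psd.epoch_times,
                                epoch_blocks=psd.block_ids)
cv = ep.loo_block_cv(psd, lane, scheme="standard", significance=False)

responses = ep.assign_presses(bundle.rsvp_events, bundle.rsvp_presses)
rc = ep.RunConfig()
acc = ep.rsvp_behavior_series(bundle.rsvp_events, bundle.rsvp_presses,
                              "accuracy", rc, cfg.block_bounds,
                              epoch_times=psd.epoch_times,
                              epoch_blocks=psd.block_ids)

res = ep.cross_task_transfer(cv.models, psd, acc)
print("per-fold-model cross-task R:",
      [f"{r:+.2f}" for r in res.per_model_r])
print(f"mean R = {res.mean_r:+.3f} +/- {res.se_r:.3f} (SE over fold models)")
print("negative R = models of lane deviation anti-track accuracy, i.e. the")
print("shared alertness state transfers across tasks")
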