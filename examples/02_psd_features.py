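"""From raw EEG to the smoothed log-PSD features the models consume.

Sliding ~3 s epochs (750 points, 500-point step), 26 Hann windows per
epoch with a 256-point FFT, a 5-sample median across windows for artifact
mitigation, log10, 1-40 Hz bins, then the same centered 90 s mean filter
that smooths the behavioral metrics.
"""
from dataclasses import replace

import numpy as np

import eegperf as ep

cfg = replace(ep.SimConfig(), n_blocks=2, block_len=240.0)
bundle = ep.simulate_session(cfg, seed=3, task="driving")

psd = ep.compute_psd(bundle.eeg)
print(f"epochs x channels x freqs: {psd.logpower.shape}")
print(f"epoch step: {np.diff(psd.epoch_times)[0]:.3f} s "
      f"(= 500/256 s); freqs {psd.freqs[0]:g}..{psd.freqs[-1]:g} Hz")

smoothed = ep.smooth_psd(psd, block_bounds=cfg.block_bounds)

# the alpha power of an informative channel follows the latent state
oz = psd.channel_index("Oz")
alpha = smoothed.logpower[:, oz, 7:12].mean(axis=1)
lat = np.interp(psd.epoch_times, bundle.truth.latent_times, bundle.truth.latent)
r = np.corrcoef(lat, alpha)[0, 1]
print(f"corr(latent alertness, Oz alpha log-power) = {r:.2f}")
print("-> band power is a readable proxy for the latent state after smoothing")
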