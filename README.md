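# eegperf

Continuous estimation of slow, endogenous fluctuations in task
performance from concurrent EEG log power spectra — a passive
brain-computer-interface analysis chain for fatigue / time-on-task
monitoring, with a fully seeded synthetic-session simulator so every
stage can be verified without recorded EEG.

**Who it is for.** Researchers building passive BCIs or studying
time-on-task decrements who want a transparent, linear, interpretable
decoding pipeline: from raw multichannel EEG and behavioral event logs
(simulated driving lane deviation; RSVP target-detection accuracy,
reaction time, and button-press duration) to a cross-validated,
significance-tested, spectrally interpretable estimate of behavior.

## The method

1. **Features.** EEG (mastoid-referenced, 256 Hz, 0.5–50 Hz) is turned
   into a moving log power spectral density: sliding 750-point (~3 s)
   epochs with a 500-point step; 26 Hann windows (125 points, 25-point
   step) per epoch, each zero-padded to a 256-point FFT; a 5-sample
   median across windows for artifact mitigation; window-averaged power
   in log10; the 1–40 Hz bins kept. Both the PSD and the behavioral
   metrics are smoothed with the same centered, block-bounded 90 s mean
   filter.
2. **Model.** For a channel subset, the 40 bins per channel are stacked
   into X (n epochs × 40k). PCA of the column-centered covariance
   retains every eigenvector v_i explaining ≥ 1 % of the variance
   (λ_i/Σλ ≥ 0.01), and ordinary least squares maps the projections to
   the behavior y:  ŷ = Σ_i β_i (x − x̄)ᵀv_i + β₀.
3. **Channel selection.** The *standard* scheme fixes the montage at the
   midline Fz, Cz, Pz, Oz. The *adaptive* scheme runs sequential forward
   floating selection (SFFS) over the 32-channel montage, maximizing the
   criterion J(X_k) = 1/RMSE of the cross-validated estimate, with
   subset sizes 1–12 and a 500-evaluation budget.
4. **Evaluation.** Leave-one-block-out cross-validation over the six
   10-minute experimental blocks; performance is Pearson's R between
   actual and estimated behavior over the whole session, plus RMSE
   normalized by the behavior's standard deviation. Significance comes
   from a permutation null: the estimate is shuffled, re-smoothed with
   the 90 s filter (so the null keeps the autocorrelation that inflates
   spurious correlations of slow signals), and correlated with the
   actual behavior; a Gaussian fit to 1000 such R values sets the
   p < 0.05 threshold.
5. **Interpretation.** Each model's per-frequency relative weight
   W(f) = (1/‖β‖) Σ_i X̂(f) v_i(f) β_i is pooled across folds and
   channels and tested against zero with Benjamini–Hochberg FDR.
6. **Transfer.** Fold models from one task are applied to the other
   task's full session, with a slope+offset rescale onto the new metric
   (which cannot change |R|).

RSVP behavior is first normalized for perceptual difficulty — the
per-image grand average across participants is subtracted and the
difference re-anchored at nominal values (accuracy 1, RT 600 ms,
duration 300 ms) — and RT/duration are adjusted for each block's target
probability using fixed cross-participant slopes (−262 and −277 ms per
unit probability).

## Worked example

```bash
python examples/03_decode_driving.py
```

prints (seeded, reproducible):

```
standard: R = +0.966  nRMSE = 0.267  threshold = 0.448  (significant, p = 0.0002)
adaptive: R = +0.943  nRMSE = 0.401  threshold = 0.446  (significant, p = 0.0002)
          channels picked by the best fold: ('Fp1', 'T8', 'Fz')
          truly informative: ('Oz', 'O2', 'Fz', 'Cz')
```

R is the correlation between the actual and the EEG-estimated lane
deviation across the whole simulated session; both schemes clear the
permutation threshold (~0.45 here — slow signals correlate spuriously,
so the bar is far above zero). nRMSE < 1 means the estimate beats the
constant-mean predictor. The other examples walk through the simulator
(`01`), the PSD features (`02`), RSVP behavioral normalization (`04`),
spectral weights (`05`), and cross-task transfer (`06`) — where a
*negative* R is the expected signature of shared alertness, since lane
deviation rises while accuracy falls as the driver fatigues.

A thin CLI mirrors the library (`eegperf simulate | psd | behavior |
fit | estimate | evaluate | transfer | weights | run-all`); see
`eegperf --help`.

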