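# Methods

This note documents the estimation pipeline, the synthetic-session
generator that serves as its test harness, and the numerical and design
choices made where the procedure left room.

## Signal model and estimator

**Preprocessing.** Recordings are referenced to the average of the two
mastoid leads, down-sampled to 256 Hz (polyphase, linear-extrapolation
edge padding) and band-pass filtered 0.5–50 Hz with a zero-phase cascade
of a 2nd-order Butterworth high-pass and an 8th-order elliptic low-pass
(0.01 dB ripple, 80 dB stopband). The elliptic design keeps the 50 Hz
passband edge while attenuating 60 Hz mains below 1 % in amplitude after
forward–backward filtering; the transition band is roughly 50–55 Hz. A
256-to-32-channel montage reduction averages each target electrode with
its listed neighbours; its purpose is robustness to single bad leads,
and spatial filtering proper is left to the PCA stage.

**PSD features.** Per channel, sliding 750-point epochs (500-point step
≈ 1.95 s) are subdivided into 26 Hann windows of 125 points (25-point
step), each zero-padded to a 256-point FFT, giving power on an exact
1 Hz grid at fs = 256. Power is the magnitude-squared one-sided FFT
without density scaling — the downstream PCA+OLS estimate is invariant
to any fixed power scaling, so the reference is arbitrary; log base 10.
A 5-sample sliding median across the window axis (shrinking at the
edges) suppresses transient artifacts before windows are averaged.
Note a geometric limit: with 125-point windows at 25-point steps, any
transient contaminates five consecutive windows, so the median filter
attenuates bursts and fully cleans their fringes but cannot null a
fully-covered run; the tests freeze this measured behavior. Epochs never
straddle block boundaries. Bins 1–40 Hz are kept; the 40 bins × k
channels are the model features.

**Smoothing.** Behavioral metrics and log-PSD are smoothed with the same
centered 90 s mean filter, applied strictly within experimental blocks.
Points within 45 s of a block edge are replaced by the first/last
fully-supported smoothed value of that block (edge padding). The window
targets slow, minutes-scale fluctuations; it also sets the effective
degrees of freedom that the significance machinery must respect.

**Regression.** Features are column-centered (means stored for test-time
reuse); the covariance eigenvectors explaining at least 1 % of total
variance are retained (if none qualifies, the single largest — a
degenerate-input guard), and behavior is regressed on the projections by
ordinary least squares with an intercept. The eigenbasis, centering
means and coefficients always come from training blocks only.

**Channel selection (adaptive scheme).** Sequential forward floating
selection over the 32-channel montage maximizes J(X_k) = 1/RMSE. The
classic step pattern is used: add the J-maximizing channel; if the newly
added channel is not the least significant member, remove the least
significant one and keep removing while doing so beats the best recorded
criterion at the smaller size. Subset sizes are capped at 12, the budget
at 500 fresh criterion evaluations (memoized repeats are free), and ties
break toward the earliest channel in the canonical cap order, making the
search deterministic.

*What J is evaluated on* is a genuine design choice: training-fit RMSE
decreases monotonically with k and would make backward steps vacuous.
The default protocol fits the (unsupervised) eigenbasis once per probe
on all training blocks and cross-validates the regression stage
leave-one-block-out, scoring the concatenated held-out predictions.
This preserves the outer train/test separation exactly, matches the
covariance-over-the-experiment spirit of the model definition, and is
five times cheaper than refitting the basis per inner fold; a strictly
nested variant (`inner-cv-nested`) and plain `train-fit` are available.

**Cross-validation and significance.** Models are trained on five of the
six blocks and tested on the sixth; block-bounded smoothing plus
block-aligned folds guarantee ~90 s temporal separation between training
and test data. Session-level performance is Pearson's R between actual
and estimated behavior plus RMSE normalized by the behavior's standard
deviation. The permutation null shuffles the estimate, re-smooths it
with the 90 s filter, and correlates with the actual behavior; mean and
variance of 1000 such correlations define a Gaussian null, and the
one-sided p < 0.05 threshold is mean + 1.645 sd (one-sided because a
model is only "working" when R > 0; a two-sided mode and an
empirical-quantile mode exist). A property of this estimator worth
knowing: with few blocks, each fold's intercept is anchored at the
*other* blocks' mean, which biases the concatenated null R negative
when behavior has strong between-block structure; the calibration study
therefore uses a null in which the latent state drives nothing.

**Spectral weights.** W(f) = (1/‖β‖) Σ_i X̂(f) v_i(f) β_i per channel
and frequency, where X̂ is the *uncentered* training-mean log power
(centering means added back). W is invariant to positive rescaling of β.
Profiles are pooled across folds and channels (with a participants axis
when several sessions are supplied), each of the 40 frequencies gets a
one-sample t-test against zero (the test the original procedure left
unnamed; t is the natural choice for pooled means), and
Benjamini–Hochberg step-up controls FDR at 0.05. Interpreting the sign
of W assumes X̂ > 0, which holds for microvolt-scale EEG (log10 power of
tens-of-µV signals is positive across 1–40 Hz).

**Cross-task transfer.** Each fold model of task A produces a complete
estimate of task B's behavior; a least-squares slope+offset maps it onto
the new metric's scale. The rescale cannot change |R|; R is reported
with the sign of the unrescaled estimate, so anti-correlated metric
pairs (lane deviation rises with drowsiness, accuracy falls) show up as
negative transfer correlations by design.

## Behavioral targets

Driving performance is |lane offset|, smoothed per block and sampled at
the PSD epoch centers by nearest time within the same block (no temporal
lag anywhere in the pipeline). RSVP presses are assigned to images with
onset 300–1000 ms before the press (boundaries inclusive); the oldest
unclaimed target in the window wins and defines RT; earlier presses
claim shared targets, later ones fall through to the false-alarm rule
(nearest non-target to 600 ms before the press, no RT recorded).
Unassignable presses are flagged, never dropped silently. Accuracy
counts every target (hit = 1/miss = 0); RT and duration use hits only.
Normalization re-anchors each response at nominal − accuracy 1, RT
600 ms, duration 300 ms − after subtracting the per-image grand average
across participants, which provably removes shared perceptual-difficulty
structure (the tests require a ≥ 5× shrinkage of between-class accuracy
spread). The target-probability adjustment subtracts the fitted linear
probability effect, slope × (p_block − 0.06), with slopes −262 ms (RT)
and −277 ms (duration) per unit probability; "applying the inverse of
the fitted slope" is read as removing the effect, with the slope, sign
and reference probability configurable since the phrasing admits more
than one reading. A per-block linear-trend report (OLS slope with
t-test) is provided for decrement counting; it is not on the estimation
path.

## The synthetic-session generator

The generator defines the study conditions for every test: a ~66-minute
session of six 10-minute blocks (one-minute breaks), 32 channels at
256 Hz in the standard cap layout.

* **Latent alertness**: an Ornstein–Uhlenbeck process sampled at 1 Hz,
  time constant 120 s (slow enough that the 90 s smoother passes most of
  its power), unit stationary variance, standardized per session; an
  optional within-block linear drift emulates within-block decrements.
* **EEG**: per channel, 1/f-shaped background noise (12 µV) plus
  band-limited theta/alpha/beta oscillations (6/8/4 µV). On the four
  informative channels the band amplitude is modulated as
  10^(gain·latent/2), so band log10 power moves linearly with the
  latent state: alpha +0.35 on Oz and O2, theta −0.35 on Fz and Cz.
  These defaults put the epoch-level correlation between the latent
  state and smoothed informative-band log power near 0.9 — a clean,
  high-SNR regime chosen so that recovery failures indicate pipeline
  defects rather than simulation noise.
* **Driving**: lane offset is an AR(1) wander (2 s time constant,
  100 Hz) whose innovation scale is 0.35 m × (1 + 0.5·latent), floored
  at 15 % — drowsier means larger deviations.
* **RSVP**: 5 Hz image stream with a blink slot every 10 s; per-block
  target class (five classes, block 6 repeating block 1) and target
  probability drawn from {0.01 … 0.11}. Per-image perceptual difficulty
  is deterministic given a shared stimulus seed (class means 0.8, 0.3,
  1.2, −0.8, −0.4 logits, within-class sd 0.6), so simulated cohorts
  share the image pool and grand-average normalization is meaningful.
  Hits follow logistic(2.2 − 0.9·latent − 1.0·difficulty); RT is
  520 + 60·latent + 40·difficulty + N(0, 60²) ms clipped to the
  response window; duration 260 + 45·latent + N(0, 40²) ms; false
  alarms at logistic(−5 + 0.4·latent) per non-target. A single button
  is simulated: presses overlapping an earlier press are dropped,
  which slightly depresses raw accuracy when targets cluster.
* **Null configuration**: every latent gain (EEG and behavioral) set to
  zero, so estimate and behavior share nothing — the condition under
  which the significance machinery is calibrated (measured one-sided
  rejection ≈ 5–6 % at α = 0.05 over 2-block sessions).

What the generator does **not** emulate: volume conduction and sensor
cross-talk, eye-blink/EMG artifact morphology, non-stationary background
spectra, inter-individual montage variability, perceptual learning.
Passing tests therefore demonstrate correctness and internal
calibration of the estimation machinery, not expected performance on
recorded EEG, where signal-to-noise is far lower and the selected
channel subsets and weights vary across individuals.

## Numerical choices

* Covariance eigendecompositions in the canonical model path are exact
  (`eigh`). Inside the channel search, the per-probe subset covariance
  is gathered from a cached training covariance, and its top eigenpairs
  are found with a deterministic (fixed-seed) randomized subspace
  iteration above dimension 200 (48-dim subspace, two power iterations,
  adaptive escalation and exact fallback when the retained count nears
  the subspace size); relative eigenvalue error is ~1e−6 at d = 480.
  The 1 % retention rule is always applied against the exact trace.
* The retained-component guard (keep the largest component when none
  reaches 1 %) handles near-isotropic inputs; zero-variance input is an
  error.
* OLS inside the search solves intercept-augmented normal equations
  assembled per fold by subtracting the held-out block's Gram
  contribution; a singular system falls back to least squares.
* The 5-point median uses an exhaustively verified min/max network;
  other odd orders use partition selection; edges shrink the window.
* Log power is floored at 1e−20 before log10 so an identically-zero
  window (e.g. a DC channel after high-pass) cannot produce −inf.
* Times are float64 seconds, session-relative; block bounds are
  half-open [start, end); all randomness flows from explicit integer
  seeds or NumPy generators, and every stochastic operation requires
  one.
* Simulated recordings are float32 and the PSD runs in the recording's
  own precision; float64 input reproduces a transparent two-loop
  reference implementation to 1e−9.

## Problem sizes used in the test suite

Unit tests run on three-block, six-channel sessions (~9 minutes of
simulated EEG). The end-to-end recovery study uses the full default
condition (20 seeds × 6 blocks × 10 min × 32 channels, adaptive scheme,
500-permutation nulls); significance calibration uses 200 two-block
null sessions; the channel-search optimality study uses 50 five-channel
instances checked against exhaustive subset enumeration. The acceptance
script analyses one full dual-task participant end to end.

## Known limitations

* The adaptive scheme's selected subsets are not unique: channels carry
  redundant information about a single latent state, so different
  subsets achieve near-identical J; only overlap with the informative
  set, not identity, is a meaningful recovery criterion.
* Single-session weight testing pools folds and channels, which mixes
  informative and uninformative channel rows and is conservative; with
  cohorts of sessions, pool per participant instead.
* The concatenated-fold correlation inherits a negative bias under the
  null when behavior has strong between-block structure (intercept
  anchoring); thresholds derived from the permutation null do not model
  this bias, making the one-sided test conservative in that regime.
* EDF/BDF import is a thin optional wrapper (`eegperf.io.read_edf`,
  requires `mne`); channel naming across vendor montages is the user's
  responsibility.
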