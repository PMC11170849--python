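# Methods

`neurogait` analyzes cue-aligned lower-limb motor sessions: multichannel
EEG plus knee-angle traces recorded while a participant prepares (MP) and
executes (ME) left- or right-foot knee movements.  Each 10-s trial is
4 s of fixation, a 3-s MP cue and a 3-s ME cue; a session holds 50 trials
per foot at 500 Hz on a 32-channel 10/20 montage.  Four feature streams
are extracted and placed on a common time axis: the movement-related
cortical potential (MRCP) at Cz, parietal–frontocentral connectivity
(PFCC) time courses, a sliding-window left/right decoding-accuracy curve,
and the averaged knee-angle trace with its gait events.

## Filtering

All filters are linear-phase windowed-sinc (Hamming) FIR designs applied
forward–backward (`scipy.signal.filtfilt` with one filter length of
reflect padding), so no stream is time-shifted by filtering — a
prerequisite for comparing latencies across streams.  Bands: 0.1–5 Hz for
the MRCP, 8–50 Hz for connectivity, 8–13 Hz for the alpha-band PFCC.
The default order is ~3.3 cycles of the low edge, capped at 1501 taps so
the filter remains applicable to 10-s trials; at the 0.1 Hz edge this cap
deliberately relaxes the transition (a full-resolution 0.1 Hz high-pass
would be longer than a trial).  Signals shorter than three filter lengths
are rejected rather than silently truncated.

## Connectivity

Functional connectivity is the sample Pearson correlation between channel
pairs over a window, aggregated into a symmetric N_c x N_c matrix with
unit diagonal (valid correlation matrices are PSD up to floating error;
this is asserted in tests).  Static connectivity uses the full 3-s phase
window (N_t = 1500 at 500 Hz).  Time-varying (TV) connectivity slides a
200-ms window with 90% overlap (step 20 ms) along the 6-s MP+ME segment:
floor((3000-100)/10)+1 = 291 windows, N_t = 100 each, with no padding.
Window timestamps are window centers relative to the MP cue.

PFCC time courses are the windowed correlations of P3–FC4 and P3–C4 on
alpha-filtered signals.  Two landmarks are reported: the first window
center after the MP cue at which the trial-averaged curve is negative
(the preparatory dysconnection onset), and the curve's peak within the ME
phase.  The peak time is refined by a local parabola fit over +-12
windows (+-240 ms): windowed correlations of narrowband signals carry
appreciable sampling noise at N_t = 100, and the fit pools it across the
peak; the refined vertex is reported when the fit is concave and lies
inside the fitted span, the raw argmax otherwise.  Trial averaging uses
plain means by default; a Fisher-z option exists.  Note that the sample
correlation estimator is slightly biased toward zero at small effective
sample sizes, so windowed alpha-band correlations under-recover large
target values by a few hundredths — within the +-0.05 control tolerance
the generator tests assert.

Per-phase summaries use only windows lying fully inside a phase;
the premovement phase is per-trial, from the ME cue to that trial's
movement onset.

## MRCP

The Cz signal is filtered to 0.1–5 Hz, each trial is baseline-corrected
by its mean over the final 1 s of fixation (the anchor that makes
absolute amplitudes comparable), and trials are averaged pointwise over
the epoch
from the MP cue to the end of ME (-3 to +3 s around the ME cue).  The
trough is the global minimum in [0, 3] s after the ME cue, ties broken
earlier.  Condition comparisons (hemiplegic vs nonhemiplegic foot) use a
two-sample t-test on per-subject trough amplitudes.

## Classification

Connectivity matrices are vectorized as the strict upper triangle
(row-major; 496 features for 32 channels) and decoded with a linear SVM
(C = 1) under seeded stratified tenfold cross-validation.  For the
291-window accuracy curve the fold assignment is computed once and reused
across windows, so curve variation reflects features rather than fold
resampling.  Feature scaling is leakage-free mean-centering fit on the
training folds.  Full z-scoring is available but off by default: the
design was revisited after observing that dividing by per-feature
standard deviations amplifies near-constant correlation features, and in
the p >> n regime (496 features, 90 training trials) the SVM then
overfits structured nuisance directions — a window containing a
single feature with a ~6-sigma class separation dropped from 0.97 to 0.61
CV accuracy under z-scoring.  Correlation features already share the
bounded [-1, 1] scale, so centering preserves their relative geometry.

The phase summary reports static MP and ME accuracies plus the
premovement accuracy: the maximum of the TV curve among windows whose
center precedes the detected movement onset (its latency is reported
relative to the onset and is non-positive by construction).  A raw
time-series baseline flattens all channels' band-filtered samples in a
window under the identical CV protocol.

## Gait

Traces are smoothed with a 50-ms moving average.  Movement onset uses a
two-stage rule: find the first time the trace exceeds the pre-cue
baseline mean by a threshold (default 5 deg) and stays above it for
100 ms, then backtrack to the last sample at or below baseline plus 10%
of the threshold.  The backtracking stage is what makes the onset
accurate: a smooth bump reaches a 5-deg threshold only ~50–90 ms after
true movement start, and the raw crossing time would carry that lag into
every downstream latency.  Onsets may be negative (anticipation of the
cue).  Gait events are the onset-to-peak delay (argmax minus onset, ties
earlier) and the peak angle above baseline.

## Synchronization and statistics

All streams are resampled onto the TV window centers (linear
interpolation for the sample-rate MRCP and knee traces; EEG-derived
curves are already on that axis), and the landmark table carries the
times computed by the owning modules — synchronization never re-estimates
a landmark.  Hemiplegic vs nonhemiplegic comparisons use the Wilcoxon
signed-rank test on paired per-window condition means (291 pairs per
session) or, cross-subject, on per-subject mean connectivity per grid
cell at p < 0.01 without multiplicity correction (a Benjamini–Hochberg
option exists, off by default).  All-zero paired differences are
degenerate: p is reported as 1 with a warning.  The percent increment is
100 x (mean_hemi - mean_nonhemi)/|mean_nonhemi| — the nonhemiplegic
condition is the baseline, so swapping conditions is antisymmetric only
up to the denominator.  The preparatory-connectivity/knee regression is
ordinary least squares of per-trial peak knee angle on per-trial mean MP
PFCC; NRMSE is the residual RMSE over the observed knee range, invariant
to affine unit changes.  Because the per-trial PFCC is estimated from
windowed correlations, it carries measurement error that attenuates the
OLS slope toward zero; the slope *sign* is recovered essentially always
under the default coupling, and unattenuated recovery is verified against
the generator's latent per-trial level.

## The synthetic generator

The generator emulates the paradigm's timing and the signal features the
pipeline measures; it is the ground-truth source for every recovery test.

* **MRCP**: a smooth negative Gaussian trough (sigma 0.30 s) with a
  positive Gaussian rebound (45% amplitude, +0.9 s), focal at Cz and
  spreading with exp(-d/0.04 m) over the standard 10/20 scalp positions,
  time-locked to each trial's movement onset with the trough nominally
  1.21 s after the ME cue.  The injected latency is defined on the
  0.1–5 Hz *filtered* waveform: the relaxed low edge feasible on 10-s
  trials reshapes the asymmetric trough/rebound pair, so the template is
  re-centered after passing it through the analysis filter.  Trial
  amplitudes jitter by 10% (sd), and hemiplegic-foot trials are 0.25 uV
  deeper.
* **PFCC control**: a shared narrowband alpha source s and its Hilbert
  quadrature H(s) are mixed into FC4/C4 as cos(D(t)) s + sin(D(t)) H(s)
  with D(t) = arccos(rho(t)), P3 carrying s itself.  Because both mixed
  channels share one envelope, the *windowed sample* correlation tracks
  rho(t) even over 2-cycle (200-ms) windows — stochastic mixing with
  independent sources controls only the long-run expectation and is far
  too noisy at this window length.  The mixing pre-compensates the
  measured background-noise power in the alpha band.  rho(t) steps from
  +|r_mp| to the negative MP target at the nominal crossing time (a
  symmetric step, so the trial-averaged curve crosses zero at that time)
  and carries a raised-cosine ME bump (half-width 0.5 s) peaking at the
  nominal peak time; a 'flat' profile (constant per phase) supports the
  correlation-control tests.  Per-trial offsets (sd 0.1) make the
  preparatory level a usable regressor, and hemiplegic trials get a
  +0.05 offset.
* **Class information**: an 8–50 Hz burst confined to the 200 ms before
  each trial's movement onset, Hann-tapered, mixed into C3 and C4 with
  the class flipping the sign on one channel only — the C3–C4
  cross-covariance is +w^2 for left and -w^2 for right trials while every
  channel's marginal distribution is class-identical.  Decoding it
  therefore requires cross-channel (connectivity) features; the
  time-series baseline stays at chance by construction.  Default strength
  1.0 x noise yields premovement accuracies near 0.8, emulating the
  premovement decodability reported for patients.  No execution-phase
  discriminability is injected by default: patient ME-phase accuracy
  reflects execution-related lateralization outside this generator's
  scope, so passing tests say nothing about real ME decoding.
* **Knee**: zero during fixation/MP, a half-sine rise from the onset
  (reaction time 0.97 s after the ME cue, Gaussian jitter sd 50 ms) to
  the peak 0.70 s later, and a matching cosine decay (default equal to
  the rise time, keeping the bump symmetric so onset jitter does not
  shift the averaged peak).  The per-trial peak is 40 deg minus
  15 deg per unit of the trial's preparatory PFCC offset, plus 2 deg of
  noise; IMU noise is 0.5 deg white.
* **Noise**: per-channel independent Gaussian noise with a 1/f amplitude
  spectrum (flat below 1 Hz), default 10 uV RMS broadband; alpha sources
  default to 10 uV RMS.

What the generator does **not** emulate: volume conduction and a common
reference, eye/muscle artifacts, non-stationary background rhythms,
execution-phase lateralization, and realistic inter-subject variability.
Recovery tests therefore validate the *pipeline's estimators*, not
clinical effect sizes.

`low_noise_config()` freezes the landmark-recovery validation conditions
(noise 0.5 uV, onset jitter 10 ms, no condition offsets): under them the
five injected latencies (1.21, 2.32, 1.60, 0.97, 0.70 s) are recovered
within one window step (20 ms), and within 10 ms for the sample-rate
trough, onset and knee events.  `reduced_montage_config()` (the nine
motor channels, 20 trials per class) keeps Monte-Carlo studies — e.g.
the 200-session regression-sign study — inside a few minutes.

## Numerical and degenerate-input conventions

* Window counts never hard-code 291; all lengths go through
  floor((n - w)/step) + 1.
* Correlation of a constant signal raises instead of returning 0.
* Accuracy-curve and PFCC peaks: raw argmax, ties to the earlier window;
  parabola refinement as described.  The premovement burst saturates the
  accuracy of every window substantially overlapping it, so its location
  is validated against the injected window as an interval, not a single
  center.
* `wilcoxon` on all-zero differences and t-tests on zero-variance equal
  groups report p = 1 rather than erroring.
* The percent-increment denominator is the nonhemiplegic mean; a zero
  baseline raises.

## Known limitations

* The 0.1 Hz low edge is nominal on 10-s epochs; very slow drifts
  (< ~1 Hz) are only partially attenuated and are instead handled by the
  pre-cue baseline correction.
* Windowed alpha-band correlations at N_t = 100 have few effective
  degrees of freedom; per-window per-trial estimates carry sd ~0.3–0.5
  and only trial averaging makes the curves interpretable.
* The regression of knee performance on *measured* PFCC is attenuated by
  estimation error in the predictor; slope magnitudes are conservative.
* EDF export is not provided (sessions are written as FIF epochs plus
  CSV tables; EDF recordings can be read via MNE and epoched by the
  caller).
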