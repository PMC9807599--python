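# Methods

This note documents the models, conventions and numerical choices behind
`smrbci`, in the package's own terms.

## The system being modelled

A sensorimotor-rhythm (SMR) brain–computer interface lets a user move a
cursor by modulating the mu rhythm (8–13 Hz) over motor cortex. Motor
imagery of one hand attenuates the contralateral mu amplitude
(event-related desynchronization, ERD); imagery of both hands attenuates it
bilaterally. The classic 1D cursor paradigm maps lateralized imagery to
left/right motion through the C4 − C3 band-amplitude difference and
bilateral imagery versus rest to up/down motion through the C4 + C3 sum.

`smrbci` implements that pipeline end to end — a generative EEG model, the
online control-signal chain, a closed-loop task simulator, the offline
analyses and the group statistics — so that every stage can be tested
against known ground truth.

## Synthetic EEG model

The generator is intentionally the simplest model whose band amplitudes are
analytically predictable:

* **Background noise.** Per-channel 1/f-shaped noise (third-order IIR pink
  filter, gain-normalized via its impulse response), spatially mixed with a
  Gaussian-falloff kernel over geodesic electrode distance, blended with a
  locally independent component (`noise_independence`, default 0.35) and
  scaled by a per-channel lognormal gain (`channel_gain_spread`, default
  0.2, log-sd units). The independent component and the gain spread exist
  because real Laplacian-filtered EEG retains local noise and real caps
  show electrode-level variance spread; without them the surface Laplacian
  cancels nearly all noise and variance-based channel screening has a
  degenerate null distribution.
* **Mu sources.** Two amplitude-modulated sinusoids peaked at C3 and C4
  (Gaussian spatial falloff, σ defaulting to one inter-electrode spacing),
  center frequency 12 Hz with a slow AR(1) jitter clipped to ±0.5 Hz, and a
  multiplicative AR(1) envelope (sd 0.25, τ = 0.3 s). ERD multiplies the
  source *amplitude* by (1 − depth), so band **power** scales as
  (1 − depth)²; this convention is asserted by a Welch-periodogram oracle.
  Condition switches are smoothed with a 100 ms ramp.
* **Occipital alpha.** A 10 Hz source peaked at Oz, active only during
  eyes-closed idling.
* **Artifacts.** Bad channels are replaced by white noise at 50× their
  pre-injection variance (configurable); blinks are 400 ms raised-cosine
  frontal-dominant deflections at Poisson times.

Default subject parameters (mu amplitude 6 µV per hemisphere, noise scale
4 µV, ERD depth 0.4) were chosen once so that closed-loop performance spans
the realistic range — chance level at zero ERD, ≈75–90 % percent valid
correct (PVC) at depths 0.1–0.3, and ≈95 % (not a ceiling) at 0.6 — rather
than saturating at 100 %.

What the generator does **not** model: volume conduction through a head
model, EMG, eye movements beyond stereotyped blinks, fatigue or drowsiness
dynamics, and learning. Tests passing on this synthetic data therefore
demonstrate the correctness of the *pipeline*, not the physiological
fidelity of any particular effect size.

## Online control-signal chain

* **Small surface Laplacian.** Center minus the mean of four neighbours;
  C3 → {FC3, CP3, C1, C5}, C4 → {FC4, CP4, C2, C6}, falling back (with a
  warning) to the four nearest montage electrodes when those labels are
  absent.
* **AR band amplitude.** Burg (maximum-entropy) fit of order 16 on a
  trailing 500 ms window; the power spectral density is evaluated on a
  0.25 Hz grid over the 3 Hz bin [10.5, 13.5] Hz and the amplitude is the
  square root of the mean power over the bin. The batch recursion is
  double-buffered and runs its error arrays in float32 (it is memory-bound
  on sliding-window batches); coefficients and residual variance accumulate
  in float64 and agree with an independent Burg implementation to ~1e-6.
  Degenerate windows (all-zero, or a fully predicted signal) yield zero
  amplitude via a floored denominator instead of NaN.

  A property worth knowing: the bin-mean AR amplitude is exactly
  scale-equivariant (scaling the window by k scales the amplitude by k) and
  rank-monotone against a fine-grid periodogram, but it is *not* linear in
  source amplitude when additive noise is held fixed — the Burg peak
  sharpens with SNR, so the estimate is superlinear at high SNR and
  sublinear at low SNR. The adaptive normalizer absorbs scale, so only
  monotonicity matters for control.
* **Control law.** C4 − C3 for left/right, C4 + C3 for up/down.
* **Normalizer.** Ring buffer of the last 750 raw values (30 s at the 40 ms
  update interval); offset = buffer mean, gain = 1/sd, recomputed every
  tick; before two values have been seen, and whenever the sd falls below a
  relative floor of 1e-8, the output is 0 (a neutral cursor) — this avoids
  startup transients dominating the first trial. The update is continuous
  per tick; whether a production system re-estimates per block instead is a
  documented open choice.

## Closed-loop cursor task

Trial structure: 2 s intertrial interval, 2 s target presentation, up to
6 s feedback; 25 trials per run; a session is 3 LR + 3 UD runs, an
intervention, then 3 + 3 again (all counts configurable, plus an optional
excluded practice run). The cursor starts at 0.5 and moves by
gain × control × 0.04 per tick; default gain 0.25 screen-widths/s (chosen
so sustained |control| = 1 crosses to a target in 1.6 s < 6 s) with target
zones [0, 0.1] and [0.9, 1]. Outcomes: *hit* (correct zone), *miss*
(opposite, invisible, target), *invalid* (timeout); PVC = 100 × hits /
(hits + misses), with an explicit undefined-PVC signal when no trial was
decided. For UD, up-velocity is proportional to −(normalized C4 + C3):
bilateral imagery suppresses the sum below its running mean and moves the
cursor up; the sign is configurable.

Two simplifications relative to a live system, both without effect on
outcomes because the EEG never depends on cursor state: the subject's
imagery condition persists to the end of the scheduled 6 s feedback window
even if the trial ends earlier (the trial record is truncated at the
crossing), and the normalizer state persists across trials within a run but
resets between runs.

Targets are balanced pseudo-random (13/12 within a 25-trial run, the
majority side alternating across runs).

## Offline analyses

Preprocessing (in order): variance-based bad-channel screening (robust z on
log channel variance, median/MAD, default threshold 5, plus a flat-channel
rule), spherical-spline interpolation of flagged channels (spline order 4,
regularization 1e-5, delegated to MNE), optional 60 Hz notch, zero-phase
4th-order Butterworth band-pass 1–100 Hz, polyphase resampling to 250 Hz,
common average reference, mean removal and linear detrend. Offline filters
are acausal by design; only the online chain is causal. ICA-based artifact
removal is out of scope — the pipeline accepts externally cleaned input.

Trial screening drops epochs whose pooled-channel log variance exceeds the
robust-z threshold *one-sided* (only abnormally large trials are artifact
candidates; a two-sided rule would discard clean low-variance trials,
because per-trial variance estimates are tightly concentrated).

Electrode power is the population-convention variance of each channel
(mean squared deviation from the channel's own mean); band maps apply a
zero-phase band-pass first (delta 1–4, theta 4–7, alpha 8–12, beta
13–30 Hz).

The offline control signal mirrors the online chain per trial: small
Laplacian at C3/C4 over the feedback window, band power in the online mu
bin [10.5, 13.5] Hz (configurable to 8–13 Hz; the mismatch between "mu
power" conventions is deliberate and documented here), C4 ∓ C3 combination,
then a z-score across all of the subject's trials with classes pooled.
Δcontrol is the difference of class means oriented so that separation in
the task's correct direction is positive: right − left for LR and
down − up for UD (the latter because of the UD sign convention above).
Whole feedback windows are used rather than sub-windows.

## Statistics

Wilcoxon signed-rank (zero differences dropped, midranks for ties,
W = min(W⁺, W⁻)), Wilcoxon rank-sum (U from pooled midranks) and Spearman
rank correlation. Exact p-values by full enumeration of the permutation
distribution conditional on the observed midranks — valid under ties — for
n ≤ 12 (signed-rank and rank-sum) and n < 10 (Spearman); otherwise normal
approximations with tie-corrected variance and a continuity correction
(configurable off), or the t approximation for Spearman. Two-sided p by
default; the signed Z follows the direction of (post − pre) and
(group A − group B). No multiple-testing correction is applied; reports
footnote the number of tests performed. Group summaries use sample
standard deviations (n − 1) and the "mean ± sd (test, Z, p)" template.

## Problem sizes used by the reference experiments

Closed-loop experiments simulate at the native 1,000 Hz acquisition rate:
chance level (40 runs, 1,000 trials), ERD monotonicity (20 runs per depth,
paired seeds) and the 20-subject Δcontrol–PVC cohort (2 runs per task per
subject, 18 offline trials per class at 250 Hz). The 200-replicate null
calibration runs full closed-loop sessions with a reduced design — one
8-trial LR run per part at 250 Hz — chosen because the type-I error of the
signed-rank test on cohort PVC changes depends only on pre/post
exchangeability, which any per-subject trial count preserves. The
calibration cohort draws ERD depths from N(0.15, 0.1) truncated to [0, 1]
(weak-to-middling performers): at the reduced design, stronger subjects
saturate at 100 % PVC in both parts, their paired differences collapse to
zero, and the zero-dropping signed-rank test becomes over-conservative —
the calibration is only informative when the differences are
non-degenerate.

A related practical note: the AR-16 estimator is noticeably cleaner at
250 Hz than at 1,000 Hz (sixteen poles cover a four-times narrower
Nyquist range), so closed-loop performance at a given ERD depth is higher
in the reduced design than at the native rate. Comparisons of absolute PVC
levels are therefore only meaningful within one sampling rate and model
order.

## Known limitations

* No head-model volume conduction; spatial structure is a Gaussian mixing
  kernel, so absolute topography sharpness is not physiological.
* The AR amplitude's SNR-dependent nonlinearity (above) means simulated
  Δcontrol magnitudes are not comparable across noise levels, only within.
* Exact-test enumeration grows as 2ⁿ / C(n, k); the n ≤ 12 switch point
  trades fidelity against runtime.
* EDF export writes whole seconds (zero-padded) and 16-bit quantization
  (~0.01 µV at typical ranges).
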