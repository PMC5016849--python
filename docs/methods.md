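# Methods

`phonoscreen` implements an acoustic classifier for pulmonary hypertension
(PH): from a 20-second phonocardiogram (PCG) recorded with a simultaneous
single-lead ECG, it isolates the second heart sound (S2) of every cardiac
cycle, summarizes each S2 with mel-frequency cepstral coefficients (MFCC),
and decides PH vs non-PH by comparing the recording's average negative
log-likelihood (NLL) under two class-conditional Gaussian mixture models.
PH is defined throughout as mean pulmonary artery pressure (mPAp) ≥ 25 mmHg.
This note records the model, its assumptions, the free parameters, and the
design choices made where the design was genuinely open.

## Why S2

Elevated pulmonary artery pressure changes the second heart sound: the
pulmonary valve closes later and more forcefully, so the pulmonary
component P2 grows louder relative to the aortic component A2 and the
A2–P2 splitting interval widens. S2 therefore carries the class signal,
and the rest of the cardiac cycle is discarded.

## Segmentation (`segmentation.py`)

S2 is located through the ECG rather than from the sound alone:

1. **R waves** — band-pass 5–25 Hz, differentiate, square, integrate over
   a 150 ms moving window, pick peaks above an adaptive threshold
   (`max(4 × median, 0.2 × max)` of the integrated trace) with a 200 ms
   refractory period, then refine each candidate to the extremum of the
   band-passed ECG within ±100 ms. The detector is deliberately
   standard and dependency-free; the two threshold constants are exposed
   in `SegmentationConfig`.
2. **T waves** — one per complete RR interval: the maximum of the 10 Hz
   low-passed ECG inside (R + 120 ms, R + 0.55 RR). This window brackets
   the physiological T location and excludes the QRS and the next P wave.
3. **S2 window** — the interval of length 0.30 × RR centered on the T
   wave (0.25 s at 72 bpm). Whether the window should be centered or
   asymmetric around T is not constrained by anything we model; centered
   is the simplest choice and keeps the window inside the cycle for
   normal T positions.
4. **S2 center** — the argmax of the short-time energy of the PCG inside
   the window. The loudness operator is a 20 ms *Hann-weighted* moving
   average of the squared 25–150 Hz band-passed PCG. A flat (boxcar)
   average would produce a plateau around an isolated transient whose
   argmax lands half a window early; the Hann taper makes the maximum
   unique and centered, which is why an impulse train is recovered with
   zero sample error.
5. **Segment** — 100 ms of raw PCG centered on the S2 center. 100 ms
   covers A2 + P2 at the widest simulated split (60 ms) plus the
   transient tails, and yields exactly 9 frames under the default
   framing. Cycles whose snippet would overrun the recording are dropped
   and counted in the log.

Times are seconds from recording start; intervals are half-open
`[start, end)`; `sample = round(time × rate)`.

## Features (`mfcc.py`)

Each segment is pre-emphasized (α = 0.97, the conventional speech
default), framed at 20 ms / 10 ms hop (50% overlap), Hamming-windowed,
and each frame is mapped through: one-sided power spectrum (FFT length =
next power of two ≥ frame length, 64 at 2 kHz) → 26 triangular mel
filters spanning 0 to Nyquist, centers equally spaced in
mel(f) = 2595 log₁₀(1 + f/700) → natural log with a floor of 1e−12 × the
frame's largest filter energy (1e−30 absolute for silent frames) →
orthonormal type-II DCT → first 13 coefficients (indices 0–12; the 0th,
energy-like coefficient is kept). No liftering and no delta features.
A 25 ms frame length is supported through `MfccConfig` as a documented
variant. With the orthonormal DCT, scaling a frame by c shifts only
coefficient 0, by 2 ln(c) √26 — a property the tests pin down.

All frames of all segments of a subject form one N×13 matrix carrying
per-row subject provenance and a configuration fingerprint; matrices
with different fingerprints refuse to concatenate, score or round-trip.

## Classification (`gmm.py`)

One 8-component full-covariance Gaussian mixture is fit per class on the
pooled training frames of that class, by EM:

* **Initialization** — k-means++ centers (seeded), uniform weights,
  global covariance for every component; 3 restarts, keeping the run
  with the best final log-likelihood. Deterministic given the seed.
* **E step** — responsibilities in log space via log-sum-exp.
* **M step** — standard weighted updates. A covariance whose smallest
  eigenvalue falls below 1e−6 is ridged up to that floor; the floor is
  applied *conditionally* rather than added every iteration, so in the
  generic well-conditioned case EM is the exact maximum-likelihood
  recursion and the recorded training log-likelihood is non-decreasing
  to numerical precision. A component whose responsibility mass
  collapses is re-seeded on a random frame with a logged warning.
* **Convergence** — relative log-likelihood change < 1e−6, max 200
  iterations.

Diagonal covariances are available for small-sample robustness; full is
the default. An identifiability guard requires N ≥ K(D+1) frames.

A subject is scored by the mean per-frame log mixture density under each
class model, negated (average NLL): averaging per-frame *log*-likelihoods
is the numerically sane reading of frame averaging and is what the
implementation uses. The subject is assigned to the model with the lower
average NLL; an exact tie predicts non-PH (a screening tool should err
toward fewer false alarms) and is logged. The continuous statistic is
`nll_ratio = nll_ph / nll_nonph`, so PH subjects score below 1.

## Evaluation (`evaluation.py`)

Cross-validation is subject-level, k = 5, stratified by class by default
(a fold can otherwise lose a class entirely at small n; an unstratified
flag exists). Within each class the surplus subjects after equal
division go to the currently smallest folds, so overall fold sizes also
differ by at most one (164 subjects → 33/33/33/33/32). Per fold both
mixtures are trained on training-fold frames only; a structural
assertion verifies that no held-out subject's frames reach a training
matrix. When mPAp values are available, a Welch t-test between training
and test mPAp is recorded per fold as a balance diagnostic. Pooled
(micro-averaged) counts are the primary result; per-fold and
macro-averaged metrics are also reported, since "averaging over folds"
is ambiguous between the two.

Confusion metrics treat PH as positive: CR = (TP+TN)/total,
FNR = FN/(FN+TP), FPR = FP/(FP+TN); a rate with an empty denominator is
reported as undefined (`None`), never as 0. The ROC sweeps the NLL-ratio
over all observed values plus ±∞ (PH called below the threshold); tied
scores move atomically, making the trapezoidal AUC exactly the
normalized Mann-Whitney U. The reader-comparison helper reports rate
differences and chi-squared two-proportion p-values; the chi-squared
choice is this package's own and its p-values agree with an exact
enumeration to ~0.02 only for reasonably balanced small tables.

## Synthetic cohorts (`synth.py`)

The generator exists so every stage can be measured against ground
truth. Per cycle it writes: an ECG R deflection (7 ms Gaussian spike
with a trailing dip) and a Gaussian T hump at 30% of the RR interval; an
S1 burst (35 Hz, σ = 15 ms) 60 ms after R; and S2 as two
Gaussian-enveloped damped sinusoids — A2 at 50 Hz and P2 at 45 Hz,
σ = 10 ms — with P2 trailing A2 by `split_map(mpap)` at amplitude ratio
`p2_gain_map(mpap)`. The default maps are linear and monotone: split
20 ms at 15 mmHg → 60 ms at 60 mmHg; P2/A2 ratio 0.4 → 1.5 over the same
range — plausible magnitudes for the known widening and loudening, where
only monotonicity actually matters to the pipeline. Heart rate is
70 ± 8 bpm between subjects (clipped to 40–120), cycle lengths jitter
lognormally (3% sd), and white noise is added per channel at 1% of the
channel's clean peak by default. Cohort mPAp values are uniform on
(28, 55) mmHg for PH and (11, 23) for normals, matching the modelled
population's class means (~41 and ~17 mmHg). Each cycle's truth
S2-center annotation is the short-time-energy argmax of the *clean* PCG,
i.e. exactly the quantity the segmenter must recover.

Deliberately not modelled: P waves and QT dynamics, murmurs and other
adventitious sounds, respiration-gated splitting, baseline wander,
sensor artifacts. Consequently, passing tests demonstrate the internal
correctness and discriminative mechanics of the pipeline — not clinical
performance on real auscultation, where S2 detection and the acoustic
class signal are both far harder.

A `null_cohort` variant draws both arms from one narrow mPAp range and
assigns arm labels arbitrarily: any classifier must perform at chance on
it, which calibrates the evaluation machinery.

## Problem sizes used by the checks

The simulation-based checks run 40+40-subject cohorts over 5 seeds for
discrimination, 20+20 over 10 seeds for null calibration, and the
acceptance script one 86+78 cohort — sizes at which the binomial noise
on a correct rate is a few percent, small against the margins being
asserted.

## Known limitations

* The R/T detectors are tuned for clean single-lead traces with upright
  R waves; inverted leads rely on the |signal| refinement and severe
  baseline wander is not handled.
* Full-covariance mixtures with 13-dimensional features need a few
  thousand training frames to be well-conditioned; the diagonal mode is
  the fallback, not an equivalent.
* The NLL-ratio threshold for the ROC is swept, but no operating point
  is selected; choosing one requires a cost model this package does not
  impose.
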