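# Methods

## Scope

`emgmh` reconstructs a surface-EMG (sEMG) muscle-health classification
analysis as a tested pipeline: multi-channel recordings of upper-limb
motions are segmented into activation bursts, 42 features are computed per
muscle channel over each burst, features are ranked and reduced with
ReliefF, and per-motion LDA/SVM/random-forest models are combined by
majority votes under leave-one-patient-out (LOPO) cross-validation.
Because no patient recordings are distributable, the package ships a
synthetic cohort generator that emulates the statistical structure such a
study assumes; every downstream claim is therefore a claim about
recoverability of planted structure, not about clinical effect sizes.

## Synthetic cohort

A cohort is `n_patients` (default 27) × 2 limbs × 10 motions (EF, EE, P,
S, WF, WE, UD, RD, HO, HC) × 3 repetitions, 7 muscle channels (BB, TBlat,
TBlong, PT, BRD, ECU, FCU) at 1925.93 Hz.  Each trial is rest–burst–rest
(defaults: 1.5 s rest, 2.0 s nominal burst, ±25 % per-trial duration
jitter).  The burst on an active channel is a unit-variance mixture of

* broadband 20–400 Hz Gaussian noise (upper edge patient-specific,
  300–400 Hz),
* a narrow spectral resonance (130 ± 22 Hz between patients, 26 Hz
  bandwidth, weight 0.5–0.7),
* a patient-idiosyncratic second narrow peak (180–320 Hz, weight
  0.25–0.55),
* a 280–400 Hz "tilt" component (weight 0.3 × patient factor 0.5–1.5),
* a biphasic-wavelet impulse train (22 s⁻¹, 3 ms width, amplitude 3.5),

band-limited to 20–400 Hz (the recording chain), shaped by a trapezoidal
envelope with raised-cosine ramps over 10 % of the burst, and scaled by
the channel's role (primary mover 1.0, synergist 0.45, quiet 0).  Baseline
noise (sd 0.02 in burst units) covers the whole trial; a 60 Hz sinusoid
can be added.  Patient offsets (amplitude ±20 %, timing ±0.2 s, firing
rate ±20 %, and the spectral-mixture parameters above) are shared by the
two limbs of a patient, mirroring the paired design.  Units are opaque;
all features are unit-covariant or unit-free.

The between-patient spectral-mixture variation is deliberate: whole-
spectrum summaries (AR coefficients, entropies) see large nuisance
variance between patients, as they do in real cohorts, so they cannot act
as free class labels whenever any spectral property is planted.

### Injury effects

`EffectSpec` modifies the injured limb only; the null spec makes the limbs
exchangeable (verified by the chance-level control).  The knobs map to
feature families as follows:

* `amplitude_shift` multiplies the envelope gain (energy features).
* `spectral_shift` (Hz) concentrates power around the spectral peak:
  the resonance bandwidth shrinks by that amount (floor 6 Hz) and its
  weight grows by `1 + shift/22` — the PSR driver.
* `spike_duration_shift` slows the dominant deflections: the broadband
  upper edge divides by the factor and the impulse wavelets widen by it.
  Detected spike durations (MSD) are half-periods of the dominant
  oscillation, so they scale with this factor.
* `spike_density_shift` multiplies the impulse rate (spike frequency and,
  weakly, MYOP).
* `complexity_shift` multiplies the burst duration — injured motions run
  slower — which grows the burst's total curve length, the quantity MFL
  measures, while every length-normalised feature is untouched.  It also
  raises the high-band tilt by the square root of the factor.

The shipped `large` profile (amplitude 1.12, spectral 20 Hz, density 0.6,
duration 2.2, complexity 1.7) is the planted-truth condition used by the
end-to-end recovery checks.  The amplitude factor compensates the
derivative-power loss of the slower oscillations, which would otherwise
hand the planted MSD/PSR signal to DASDV through the centroid; without it
DASDV (a pure derivative-energy feature) shadows any slow-oscillation
plant.  Effect magnitudes are calibration knobs of the generator, not
estimates of clinical effect sizes.

## Preprocessing and segmentation

Onset detection runs on a conditioned envelope: Teager–Kaiser energy
operator Ψ[x](n) = x²(n) − x(n+1)x(n−1) (interior samples only; the two
boundary samples are dropped and indices are reported in original
coordinates), rectification, and a zero-phase 2nd-order Butterworth 50 Hz
low-pass.  The double threshold declares an onset when 25 consecutive
samples (th2) exceed th1 = mean + 15 sd of the first 0.5 s of the trial
(the baseline window, assumed rest); both statistics are taken on the
conditioned envelope, the quantity being thresholded.  The offset mirrors
the rule (25 consecutive sub-th1 samples), else the trial end with a
`truncated` flag.  Because the 15-sigma trigger fires partway up the
ramp, the reported onset walks back to where the envelope last rose
through baseline mean + 0.5 sd; this refinement is on by default and can
be disabled.  Detections shorter than 0.25 s are treated as supra-
threshold blips, flagged, and skipped.

The detection envelope is the sum over channels; when the motion is known
the pipeline restricts the sum to that motion's primary movers (quiet
channels only dilute the envelope).  All channels are cut at the same
indices.  Feature extraction runs on a separate path: zero-phase
2nd-order Butterworth 20–400 Hz band-pass plus a 60 Hz notch (Q = 30);
"2nd order" refers to the design order before forward–backward doubling.
Failed or truncated detections become QC flags, never silent drops, and a
manifest may carry hand-edited onset/offset pairs that take precedence —
the programmatic stand-in for manual resegmentation.

On 200 default-condition trials, ≥95 % of detected onsets fall within
25 ms of the generator's ground truth (the acceptance suite recomputes
this).  Under the `large` effect the injured bursts ramp more slowly and
onsets degrade to roughly 60 % within 25 ms; segments remain intact, and
the QC table records the errors.

## Features

All 42 features are computed per channel over the whole motion segment;
definitions follow the standard formulations in the myoelectric-control
literature and each is frozen against an independently coded brute-force
oracle (plain loops, direct DFT, full distance matrices) in the test
suite.  Choices the literature leaves open:

* Thresholds for ZC, SSC, WAMP, MYOP default to 0.01 × segment RMS
  (relative, hence scale-robust; absolute overrides available).  A
  consequence worth knowing: on Gaussian-like bursts MYOP saturates near
  0.99 and carries little information — FS4's discriminative power in the
  planted-effect checks comes from MFL.
* MAVS keeps its K−1 = 2 dimensions (between-window MAV differences,
  K = 3 equal windows); MTW/MHW report the mean of the K per-window
  windowed energies (trapezoid with 25 % linear ramps, Hamming).
* PSD is a one-sided boxcar periodogram with mean removal (Welch
  optional); PSR half-band 10 Hz; FR split 100 Hz.
* AR coefficients by Burg's method (`statsmodels`), prediction convention;
  cepstral coefficients via c₁ = −a₁, c_p = −a_p − Σ (1 − m/p) a_m c_{p−m}
  with a = −ρ, verified against the log-series expansion.
* ApEn/SampEn use m = 2, r = 0.2 sd; the kernels are exact quadratic
  template counts reorganised (sorting on the first template coordinate,
  pair symmetry, early exit) and numba-compiled.
* HFD uses k_max = 8; DFA uses 10 log-spaced scales in [4, N/4] with
  linear detrending; MFL = log₁₀ √Σ(Δx)², guarded to a missing sentinel
  for constant segments.
* Spike analysis thresholds at baseline mean + 1.96 sd (pre-onset
  samples); a spike is a supra-threshold excursion extended to its
  bounding local minima; amplitude is peak-to-trough (flag to switch),
  duration trough-to-trough, slope max |Δx|·fs, peaks-per-spike counts
  supra-threshold local maxima; MSF is spikes per segment second.
* VAR uses the raw second moment Σx²/(N−1), the common convention for
  zero-mean sEMG.
* Missing values (degenerate segments) become NaN sentinels; rows with
  any missing cell are flagged, and imputation happens per training fold
  (column medians) inside the classifiers.

Feature matrices carry (patient, limb, motion, repetition) identity
columns; no cross-limb normalisation is applied, so the healthy and
injured limbs of a patient remain directly comparable.

## Feature selection

ReliefF (k = 10 nearest hits/misses, all instances sampled, per-feature
range-normalised Manhattan distance) follows the conventional weight
direction: a good feature accumulates +diff to misses and −diff to hits,
giving weights in [−1, 1] with positive = discriminative.  Multi-
dimensional features and the seven per-muscle copies are ranked as blocks
by the maximum column weight, so selection returns whole named features.
"Consistently ranked among the best for all motions" is operationalised
as the lowest mean rank across the ten per-motion ReliefF runs, ties
broken by mean weight.  A stability score (agreement of the selected set
across subsampled reruns) flags selections that are noise artifacts.
Because selecting on the same data that is then classified is upward
biased, the end-to-end checks always evaluate on freshly simulated
cohorts.

## Classification and voting

Models: LDA (lsqr solver with shrinkage 10⁻⁴ — a small ridge on the pooled
covariance, needed when feature count approaches instance count), linear
SVM (C = 1, training-fold standardisation), random forest (200 trees,
√d features per split, fixed seed).  Evaluation is LOPO: each fold holds
out all instances of one patient, both limbs, so patient identity cannot
leak; imputation, standardisation and model fits happen strictly inside
the training fold (audited by a hash check over fitted statistics).

Votes aggregate the ten per-motion predictions per instance key
(patient, limb, repetition); a `per_limb` mode additionally collapses the
three repetitions.  The vote unit is instance-level by default because
accuracy denominators of interest (e.g. 162 = 27 × 2 × 3) are instance
counts.  Schemes: plain majority over all motions; plain majority over
the top motions (EF, EE, P, S, WF, UD, HC); weighted vote where each
motion contributes its model accuracy and the label with the larger sum
wins.  Weighted-vote weights are recomputed by an inner LOPO inside each
training fold by default (leak-free); an in-sample mode that weights by
whole-dataset accuracies is available for comparison (it leaks and is
not the default).  An unweighted
tie falls back to the weighted rule when weights exist, else to the
injured class — the conservative call in a screening context.  The
three-class labelling scheme (healthy / 0–6 weeks / 7+ weeks) only
relabels instances; LDA and RF are natively multi-class and the SVM uses
one-vs-rest.  Ordinal patient covariates (sex, age category 1–3 with
edges 30/45 years, BMI category 1–3 with edges 25/30, time-since-injury
category) can be appended identically to both limbs.

## Problem sizes and runtime choices

The chance-level control runs at the study scale (27 patients, 1620
trials) because FS4 extraction is linear-time.  The planted-effect
end-to-end check uses 12 patients (720 segments), a desk-scale size at
which FS5 extraction (dominated by the quadratic entropies) completes in
a few minutes; ReliefF's k = 10 needs more than 10 instances per class
per motion, which 12 patients (36 per class) satisfies with margin.
AR recovery uses N = 4000 samples and 50 seeds; segmentation recovery
uses 200 trials.

## What passing does and does not show

The generator produces Gaussian interference-pattern bursts with planted,
separable class effects and exchangeable limbs under the null.  Real sEMG
adds nonstationarity within bursts, electrode and skin-impedance
variation, crosstalk between channels, handedness asymmetries, and
patient populations whose injured-limb changes are heterogeneous in both
direction and size.  Passing the recovery checks therefore demonstrates
that the pipeline is correct and leak-free and that planted structure of
the stated kind is recoverable at the stated sizes — not that comparable
accuracies would be reached on clinical recordings, and accuracies reported for
real patient cohorts are not reproducible from synthetic data.  Known limitations: MYOP's relative threshold saturates (above);
onset localisation degrades for very slow ramps; spike-shape statistics
on strongly supra-threshold bursts measure dominant-oscillation
morphology rather than isolated motor-unit potentials.
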