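# emgmh — surface-EMG muscle-health classification

`emgmh` is a tested, reusable implementation of an sEMG analysis pipeline
for distinguishing healthy from injured upper limbs in a paired cohort
(each patient contributes both limbs, performing ten standard
rehabilitation motions with seven muscles recorded).  It covers the whole
chain:

1. **Synthetic cohorts** — paired recordings (patients × limbs × motions ×
   repetitions, 7 channels at 1925.93 Hz) with burst-like activations on a
   noise baseline and controllable healthy-vs-injured effect sizes in
   amplitude, spectral concentration, spike morphology and waveform
   complexity.  With a zero effect the limbs are statistically
   exchangeable, so the whole downstream pipeline has a built-in negative
   control.
2. **Segmentation** — Teager–Kaiser energy operator (TKEO) conditioning,
   Ψ[x(n)] = x²(n) − x(n+1)·x(n−1), rectification and 50 Hz low-pass,
   then double-threshold onset detection: activation starts when th2 = 25
   consecutive envelope samples exceed th1 = b̄ + 15σ of the rest
   baseline.  Features are extracted from a separate 20–400 Hz band-pass +
   60 Hz notch path.
3. **Features** — the 42 standard sEMG features (time domain, multi-window,
   frequency domain, spike shape analysis, AR/cepstral coefficients,
   entropies, fractal measures, higher-order statistics), one value (or
   coefficient block) per muscle per motion segment, plus the named
   feature sets FS1 = {MAV, SSC, WL, ZC}, FS2 = {RMS, AR2},
   FS3 = {MSA, MSF, MSS, MNPPS, MSD}, FS4 = {MFL, MYOP},
   FS5 = {LOG, DASDV, MYOP, MAVS, PSR, AR4, ApEn, MFL, MSD} and the
   ReliefF-reduced FS5 = {PSR, MFL, MSD}.
4. **Selection** — ReliefF (k = 10) weighting in [−1, 1] per motion,
   block-level ranking, mean-rank aggregation across motions; individual
   feature ranking by across-motion majority-vote accuracy.
5. **Classification** — per-motion LDA / linear-SVM / random-forest (200
   trees) models under leave-one-patient-out cross-validation, aggregated
   per instance by plain, top-motion (EF, EE, P, S, WF, UD, HC) and
   accuracy-weighted majority votes (weights computed leak-free inside
   each training fold).

Every feature is frozen against an independently coded brute-force oracle,
and all cross-validation statistics are audited for leakage.  See
`docs/methods.md` for the model, its assumptions, and what passing tests
do and do not show about real recordings.

## Worked example

Run the analysis scripts in order (they write under `results/`):

```bash
python analysis/01_simulate_cohort.py     # 720 trials, 12 patients
python analysis/02_segment_trials.py
python analysis/03_extract_features.py    # FS4 and FS5 matrices
python analysis/04_select_features.py
python analysis/05_classify_and_vote.py --feature-sets FS4 --classifiers lda
python analysis/06_chance_control.py      # zero-effect negative control
```

With the default large planted effect, `02` reports onset recovery
against the generator's ground truth (62.6 % within 25 ms on this cohort —
the injured bursts ramp slowly; on default-condition cohorts recovery is
≥ 95 %, which the acceptance checks verify), and `04` prints the ReliefF
reduction of FS5:

```
mean rank across motions:
PSR      1.0
MFL      2.0
MSD      3.3
ApEn     3.9
...
selected (top 3): PSR, MFL, MSD
```

meaning the per-motion ReliefF runs consistently rank exactly the three
planted features first.  `05` prints the FS4 + LDA accuracies:

```
FS4 + lda: per-motion 88.9-100.0%, weighted vote 100.0%
```

(with this strong, clean planted effect the weighted vote saturates;
real-data accuracies are far lower).  The chance control (`06`) prints,
for a zero-effect cohort with permuted labels:

```
majority-vote accuracy: 54.3% over 162 instances
99% binomial chance band: 40.1-59.9% -> inside the band
```

i.e. the full pipeline sits at the 50 % baseline when there is nothing to
find.

There is also a CLI (`emgmh simulate|segment|extract|select|evaluate|run`)
wrapping the same library calls.

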