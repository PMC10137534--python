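# Methods

`comaqeeg` implements a quantitative-EEG pipeline for discriminating deep-coma
consciousness levels (Glasgow Coma Scale, GCS, 3–8) from four-channel bipolar
EEG (F3-F4, C3-C4, T3-T4, P3-P4, 500 Hz) recorded under a staged bedside
protocol, together with a synthetic cohort generator that makes every stage of
the analysis testable without patient data. This note documents the model
assumptions, the tunable parameters, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Recording protocol and segmentation

The protocol alternates rest and stimulus stages: 5 min rest, 5 min nurse
interaction (auditory + tactile stimuli), 10 min rest, 5 min family
interaction, 10 min rest — 35 min in total. Each recording is expanded into up
to nine analysis segments: the three 5-min stages contribute one full window
each, and each 10-min rest contributes its first five minutes (F5), its second
five minutes (S5), and the total ten minutes (T10). Windows are half-open
`[start, start + duration)` in seconds from record start.

Rest stages at the bedside are not always exactly ten minutes. Segmentation
therefore *drops* any window shorter than its nominal length and never pads:
a truncated rest keeps only its F5 window (S5 is treated as undefined whenever
the full ten minutes are unavailable, since the T10 window it completes cannot
be formed). A cohort with occasional truncated rests consequently yields fewer
than `9 × n_patients` instances, mirroring the instance bookkeeping of real
staged recordings.

## Preprocessing

* **Notch**: second-order IIR at 50 Hz, quality factor 30 (default), applied
  forward–backward (`filtfilt`), so mains interference is removed with zero
  phase shift.
* **Lowpass**: 101-tap (at 500 Hz) Hamming-window FIR, cutoff 30 Hz, applied
  in two passes (forward and time-reversed) for zero net delay.
* **Band decomposition**: Hamming-window FIR bandpass per sub-band
  (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz), zero-phase as above.
  The bandpass length is 1001 taps at 500 Hz: the Hamming transition width is
  roughly `3.3 · fs / taps` ≈ 1.6 Hz, which keeps the interior of the 5-Hz-wide
  alpha band flat. A 501-tap design (transition ≈ 3.3 Hz) measurably attenuates
  energy at 9 and 12 Hz and loses ~7 % of strictly in-band alpha energy, which
  is why the longer design is used. Filter lengths scale with the sampling rate
  so transition widths are stable in Hz.
* **Edge handling**: signals are reflect-padded by one filter length before
  filtering, so startup transients do not bias segment energies. All filters
  are verified zero-phase (impulse-train cross-correlation peaks at lag 0).

## Spectral features

For each of the 4 channels × 4 bands, ten descriptors are computed; the
160-vector is ordered channel-major, bands ascending in frequency, features in
the fixed order *Energy, Maxf, Maxp, AUC1, AUC2, Rate1, Rate2, Rate3, NPower,
TPower*. The ordering is frozen for file compatibility.

* **Energy** is the Parseval energy of the band-filtered time series,
  `Ex = (1/N) Σ_k |S(k)|² = Σ_n s(n)²` (µV²·sample). It is computed in the
  frequency domain from the segment's DFT, not by integrating the PSD.
* The remaining nine descriptors come from the **Welch PSD** of the
  band-filtered samples, restricted to the band (inclusive bin ends). The
  estimator averages Hamming-tapered periodograms over 50 %-overlapping
  frames; defaults are 256-sample frames zero-padded to 1024 FFT points,
  giving a ~0.49 Hz grid at 500 Hz so the 0.5 Hz delta edge is representable.
  The PSD is density-scaled (µV²/Hz, window-power normalized), so its integral
  estimates signal variance for white noise. The implementation is vectorized
  over frames and agrees with `scipy.signal.welch` to machine precision (a
  test enforces this, plus bin-for-bin equality with a brute-force periodogram
  for a single full-length rectangular window).
* **Maxf/Maxp**: the peak PSD value in the band and its frequency; ties break
  toward the lowest frequency.
* **AUC1/AUC2**: trapezoidal areas under the band PSD from the band's lower
  edge to the peak (A1) and from the peak to the upper edge (A2). The peak bin
  is shared, so `A1 + A2` equals the total band area exactly. `Rate1 =
  A1/(A1+A2)`, `Rate2 = A1/A2`, `Rate3 = A2/(A1+A2)`. When the peak falls on
  the band's last bin, `A2 = 0` and Rate2 is stored as NaN (never silently
  zeroed); NaNs are dropped pairwise in statistics and imputed per-class-median
  before SMOTE and classification.
* **NPower/TPower**: `TPower = Σ_f P_f²` and `NPower = TPower / fs`; the
  identity `TPower = fs · NPower` holds exactly.

Scaling a segment by `c > 0` scales Energy, Maxp, A1, A2 by `c²`, NPower and
TPower by `c⁴`, and leaves Maxf and the three ratios unchanged; the test suite
enforces this monotonicity.

## Statistical screen

Features of coma EEG are heavily skewed, so the screen is nonparametric: a
Kolmogorov–Smirnov normality gate at α = 0.05 (against a normal with
*estimated* mean and sd — the Lilliefors caveat applies: tabulated p-values
are only approximate under estimation), then a tie-corrected Kruskal–Wallis
test per feature across the six GCS groups, then Dunn's pairwise z-tests with
tie correction and Bonferroni adjustment over the 15 group pairs of that
feature (not across the 160-feature family). All-identical samples return
`H = 0, p = 1` by convention.

Instances are pooled per segment as independent observations by default,
mirroring the pooled-instance study design; this pseudo-replicates patients
(nine windows per patient, with each T10 literally the concatenation of its F5
and S5), so a per-patient aggregation mode is provided for conservative use.
For the same reason, the pipeline's *type-I calibration check* runs on the
seven non-overlapping windows only and on a null cohort with zero
inter-patient variability — with T10 windows or patient-level random effects
included, within-group dependence inflates the Kruskal–Wallis false-positive
rate by construction, which would say nothing about the test implementation.
Note also that the 160 per-feature p-values share instances and are therefore
mutually correlated; the binomial reference bounds used by the calibration
check treat them as independent and thus understate the spread of the
significant-fraction count somewhat.

## SMOTE balancing

Class imbalance is corrected by synthetic minority oversampling:
`x_new = x_i + (x_knn − x_i) · w` with `w ~ U[0, 1]` and `x_knn` drawn
uniformly from the `K = 5` Euclidean nearest same-class neighbors of `x_i`
(the query point excluded). A class oversampled by `p` percent emits
`floor(n · p / 100)` synthetic vectors, parents cycled in order — with class
sizes (74, 36, 18) and increases (8 %, 120 %, 340 %) every class lands on
exactly 79 instances. A plan-arithmetic audit recomputes any stated balancing
table under the floor rule and flags inconsistent rows (a stated 57 → 81 at
40 % is arithmetically impossible: `57 + floor(22.8) = 79`). Distances are
computed on raw features by default (a standardize-first option exists);
originals are preserved and ordered first; class counts never decrease.

Two pipeline modes exist because balancing-then-cross-validating leaks
synthetic copies of training points into test folds: `global` balances
the full table once before CV (and logs a warning), `leak-free` balances
inside each training fold only. The global mode is the default since it is
what a balance-then-evaluate analysis does in practice; its headline numbers
are optimistic by construction.

## Classifiers and evaluation

Four scikit-learn families behind one interface: Random Forest (100 trees),
1-NN (Euclidean), 30 bagged decision trees, and an SVM with inhomogeneous
cubic polynomial kernel (`gamma='scale'`, `coef0=1`). Distance/margin-based
families (kNN, SVM) receive z-scored features using training-fold statistics;
tree ensembles take raw features. All families receive per-feature median
imputation for the NaN Rate2 sentinel.

Evaluation pools held-out predictions over stratified k-fold CV (default
k = 20) into one 6×6 confusion matrix. Per class, one-vs-rest counts (TP the
diagonal cell, FN the rest of the row, FP the rest of the column, TN the
remainder) give sensitivity, specificity, precision, F-score
(β = 1 by default: the harmonic mean of precision and sensitivity) and
G-mean (√(sensitivity × specificity)); overall accuracy is trace/total. The
headline single numbers are macro averages (the averaging scheme for
single-value reports is otherwise underdetermined); weighted averages are also
reported. Zero-denominator metrics are NaN with a log entry. One-vs-rest ROC
curves per class come from a threshold sweep of per-class scores with
trapezoidal AUC.

Leave-one-patient-out CV holds out all segments of one patient per fold and
assigns the patient the majority vote over their segment predictions (ties
break toward the smallest label), preventing within-patient leakage.

## Synthetic cohort generator

The generator emulates the *statistical* structure the pipeline consumes —
band-power composition, protocol staging, stage reactivity, truncation, class
proportions — not EEG morphology. Each channel is a sum of band-limited
Gaussian processes: white noise shaped by an FIR filter confined to the band
(with a spectral emphasis at a configurable in-band peak frequency), rescaled
to its exact target energy, plus a broadband 0.5–30 Hz noise floor
(0.2 µV²/sample by default).

Per-level profiles fix, for every (channel, band), a target per-sample mean
square power in µV² (a window of `n` samples then has expected Parseval energy
`target · n`; the µV² scale is arbitrary since coma band-energy tables carry
no absolute calibration — only the orderings are meaningful). The shipped
defaults encode the qualitative structure reported for this population:

* GCS 3 holds the strict minimum power for every channel and band
  (global suppression in the deepest coma);
* GCS 4 emphasizes parietal/temporal, GCS 5 central/temporal, GCS 6–7
  temporal channels; GCS 8 is moderate overall with a strong frontal
  (and central) beta boost;
* in-band spectral peaks rise with GCS (e.g. alpha 8.6 → 11.5 Hz);
* for GCS ≥ 6 the interaction stages (nurse, family) multiply alpha+beta
  power by a per-level gain (1.15–1.35) and shift the alpha/beta peak up by
  0.5 Hz, emulating stimulus reactivity at lighter coma levels.

Baseline band powers are delta 20, theta 4, alpha 1.5, beta 0.6 µV²/sample —
delta-dominant, ~10 µV RMS overall, a realistic amplitude scale for
low-reactivity EEG. Per-patient heterogeneity is a log-normal factor
(σ = 0.15) drawn once per (channel, band) per patient. Long rest stages are
truncated to 8 min with probability 0.04 per rest (keeping the leading
portion), so a 39-patient cohort loses about six of its 351 nominal segments —
the same order of shortfall as a staged ICU protocol. Patient seeds derive
from the master seed as `SeedSequence(master_seed, spawn_key=(patient_index,))`,
making the cohort a pure function of its configuration.

Default class sizes are (8, 4, 9, 9, 7, 2) patients for GCS 3–8 — the study
population's imbalance, including the rare lightest-coma class.

**What passing tests show — and not.** Because the profiles are well
separated and within-class variability is mild, recovery experiments (energy
ordering, ≥ 0.90 CV accuracy, SMOTE improving minority sensitivity) verify
that the *pipeline machinery* is correct: calibrated generation, faithful
feature extraction, sound CV accounting. They do not estimate achievable
accuracy on real coma EEG, where artifacts, nonstationarity, medication
effects and overlapping spectra will dominate.

## Problem sizes used in the shipped experiments

The test-suite experiments choose sizes at which their statistical checks are
informative while the whole suite stays comfortably runnable on a laptop
core: unit tests run a 1:10-scaled schedule at 128 Hz; the recovery experiment
uses a full-scale cohort (500 Hz, 35 min) of 43 patients — the study's class
shape with the two smallest classes raised to a 5-patient floor, since
20-fold stratification needs ≥ 20 instances per class; the null-calibration
experiment pools 160 features × 3 replicate null cohorts of 12 patients
(two per level, giving 14 independent instances per group; replicate seeds
fixed in advance at 101–103).

## Known limitations

* No artifact model (eye movement, ECG, electrode pops) and no physiological
  microstructure; the generator is a band-power emulator.
* The Welch frame length (256) is a package default, not an identified
  property of the original analysis, which reported only power-of-two frame
  candidates and 50 % overlap; it is config-exposed.
* The KS gate uses estimated parameters without a Lilliefors correction.
* `global` balancing leaks by design (see above); compare both modes
  before quoting numbers.
* EDF quantization (16-bit over the per-channel physical range) bounds
  round-trip error at one step; features extracted from written-then-read
  cohorts differ at that noise level from in-memory ones.
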