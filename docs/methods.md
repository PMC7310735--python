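# Methods

This note documents the models, conventions and numerical choices behind
`anxio`, in the order the pipeline runs.

## Sessions and coordinates

A subject contributes two sessions: a biofeedback *training* session whose
5-minute resting phase supplies all normalization references, and an
*exposure* session (1-minute demo clip, sixteen 1-minute video clips, an
arousal rating on a 1–4 scale after every fourth clip, a final 5-minute
rest). Time is in seconds from session start; segments and windows are
half-open intervals [start, end), which makes window tiling unambiguous.
Segments need not be contiguous — the layout carries explicit per-segment
times, so protocol pauses (e.g. while a rating is collected) are simply
unscripted gaps. Channels are ECG (arbitrary voltage units), EDA (µS) and
RSP (% chest displacement), nominally 100 Hz.

On disk a session is a `t,ecg,eda,rsp` CSV (one row per tick, `%.17g`
precision so samples round-trip bit-exactly) with a JSON sidecar for the
layout and ratings. OpenSignals-style text is read-only convenience.

## Resting baselines

`compute_baseline` anchors at the end of the rest segment and spans either
the last 3 minutes (clip-based and subjective labeling) or the full 5
minutes (subject-based labeling). Heart rate and breathing rate are
referenced to their resting means; EDA uses the resting minimum/maximum
(range correction). The EDA extrema are taken on the 1.5 Hz low-pass
filtered signal, not the raw one, so a single noise spike cannot define the
range.

## ECG

Pan–Tompkins with canonical internals: zero-phase Butterworth band-pass
5–12 Hz, derivative, squaring, 150 ms moving-window integration, candidate
peaks at a 200 ms refractory spacing, adaptive signal/noise levels with
0.125/0.875 (accepted) and 0.25/0.75 (search-back) update weights, decision
threshold *noise + 0.25·(signal − noise)*, and search-back at 1.66× the
running 8-beat RR mean (1 s assumed before any interval exists — without a
default the detector cannot recover from an initialization transient that
sets the threshold above the steady-state beat energy). Accepted
integration peaks are refined to the band-passed maximum in the preceding
150 ms. A flat signal yields zero peaks without error; input under 5 s is
an error.

Intervals outside 300–2000 ms are discarded before they become
normal-to-normal intervals ("normal" implies artifact/ectopy exclusion); an
interval belongs to a window iff its ending peak lies in the window.

Feature conventions:

- The HR series is beat-wise (one value per interval, stamped at the
  interval's ending peak), not resampled to uniform time.
- NFD/NSD operate on the within-window z-score (x − μ_w)/σ_w with the
  sample (N−1) standard deviation; σ_w = 0 defines NFD = NSD = 0.
- HRV/BRV is the mean of *signed* successive interval differences; it
  telescopes to (last − first)/N and flips sign under time reversal. This
  is kept exactly as defined (tests pin the behavior); rMSSD is the
  conventional sign-insensitive statistic alongside it.
- NN50/pNN50/pNN20 count successive differences whose magnitude is **at or
  above** the threshold, divided by the number of successive differences
  (N−1). The boundary convention (≥, not >) matters only for the
  measure-zero case of a difference exactly at the threshold and matches
  the package's documented worked example (diffs 10, −20, 15 ms → pNN20 =
  1/3). A `count_intervals` flag exposes, for audit only, the literal
  variant that counts intervals themselves above the threshold.
- Windows with fewer than 3 intervals flag all interval statistics as
  missing — never silently zero.

## EDA

Tonic: zero-phase 2nd-order Butterworth low-pass, 1.5 Hz. Phasic:
zero-phase 2nd-order high-pass at 0.05 Hz applied to the *denoised*
(low-passed) signal — denoise-then-detrend keeps sub-threshold sensor
noise from generating candidate peaks.

Orienting responses: local phasic maxima whose rise from the onset (the
preceding local minimum, capped at 5 s before the peak) reaches 0.03 µS.
Two robustness rules reject artifacts of the zero-phase high-pass, which
undershoots and then slowly rebounds after every large response: the
onset-to-peak rise must fit in 5 s (true SCR rise times are 0.5–5 s), and
the peak itself must stand at least half the threshold above the detrended
zero line (rebound "peaks" sit at or below it). The offset is the
half-recovery point — the first sample after the peak below onset + 50% of
the magnitude — capped at 10 s. Overlapping responses split at the
intervening local minimum. With no response in a window, mean magnitude
and duration are missing, not zero.

The 0.03 threshold is read in µS; a threshold of 0.03 whole siemens would
exceed any physiological skin conductance by orders of magnitude.

## RSP

Band-pass 0.1–0.4 Hz (6–24 breaths/min; a literal 24 Hz upper cutoff is
available behind a flag for comparison) and peak picking with a 2.0 s
minimum spacing. The spacing must sit strictly below the 2.5 s period of
the fastest in-band breathing: a spacing equal to the period deletes
alternate peaks as soon as timing jitters by one sample. Interval-based
features mirror the ECG conventions; 10-second windows regularly contain
fewer than three breaths, in which case the interval statistics are flagged
missing. The respiration channel is optional everywhere except its own
operations, and the recommended feature set excludes it.

## Labeling

Clip-based (HR1/EDA1): clips ranked by the cohort mean of the
baseline-normalized signal; top 3 = high, ranks 7–9 = medium (the middle
of the 16-clip ranking; the choice of "three clips with medium average
values" is operationalized as the central ranks), last 3 rest minutes =
low. One map for the whole cohort. Subject-based (HR2/EDA2): individual
8/8 split, full 5-minute rest = low — which forces the 38%/38%/24% class
shares (8, 8 and 5 labeled minutes of 21). Subjective (SB): only the clip
right before each rating is labeled, ratings {3,4} → high, {1,2} → medium,
last 3 rest minutes = low. Ranking ties break by ascending clip index and
are logged. Windows tile each labeled segment from its start;
sub-window remainders are discarded; two-level configurations drop
'medium'. The demo clip and the post-exposure rest are never labeled.

## Feature matrix

25 canonical columns (11 ECG, 7 RSP, 7 EDA) in fixed order; the final
six-feature subset is `FINAL_SIX`. Structurally missing values are imputed
as 0 with a parallel boolean mask (classifiers need complete rows; the mask
preserves the information). Extraction is *causal*: each window's records
are truncated at the window end before any filtering or detection, and the
on-line playback engine calls the same routine — bit-exact off-line/on-line
equality holds by construction rather than by tolerance. The cost is that
batch extraction reprocesses a growing prefix per window; at the problem
sizes used here (40-subject cohorts, 10-second windows) a full cohort
extracts in well under a minute.

## Classifiers and validation

Nine configurations: Gini decision tree with at most 100 splits
(`max_leaf_nodes = 101`), LDA, QDA (singular class covariances raise an
explicit error suggesting regularization), Euclidean kNN with k = 1 and
10, SVMs with linear and quadratic kernels at box constraint 1 (the
quadratic kernel is the inhomogeneous (1 + x·y)²; the homogeneous variant
cannot separate mean-shifted classes), a naive Bayes whose class
conditionals are per-feature Gaussian kernel density estimates with
Silverman bandwidths, and bagged trees (30 fully grown Gini trees on
bootstrap resamples). A printed learning rate and subspace dimension for
bagging are inert for that algorithm and are recorded as metadata only.
Distance- and kernel-based families are wrapped in a standardizing pipeline
fitted on training folds only; tree families take raw features.

Cross-validation pools out-of-fold predictions from stratified 10-fold
splits into one confusion matrix (rows = true class, canonical order
low/medium/high) and derives accuracy, per-class true rates — implemented
as recall, diagonal over row sum, with precision also reported since the
verbal definition of a "true rate" admits either reading — one-vs-rest
ROC/AUC from the pooled class scores, and Cohen's kappa with Landis–Koch
bands ([0, .20] slight, (.20, .40] fair, (.40, .60] moderate, (.60, .80]
substantial, (.80, 1] almost perfect; κ < 0 = no agreement). When a class
has fewer members than folds, plain shuffled folding replaces
stratification with a warning (n = k reduces to leave-one-out). Window
-level folding places windows of one subject in both train and test folds;
`groups=` switches to leakage-safe grouped folding. Sequential forward
selection is a greedy wrapper on CV accuracy that stops at the first
non-strict improvement, starting from the majority-class share. Model
selection ranks by balanced per-class rates (spread ≤ 0.25), then accuracy,
then fewer features.

## Simulator

The generator emulates the study conditions: 100 Hz, the session layouts
above, and per-subject latent arousal (rest = low; by default 8 random
clips high, 8 medium; the demo clip medium). Arousal scales every effect
through weights low = 0, medium = 0.5, high = 1.

- **ECG**: RR intervals from a segment-dependent mean 60000/(HR_rest +
  ΔHR·w) with AR(1) jitter (coefficient 0.8, stationary SD 40 ms at rest,
  shrunk to 60% at full arousal — HRV falls under stress), rendered as
  Gaussian QRS bumps (σ = 12 ms, amplitude 1) plus 0.3 Hz baseline wander
  and white noise (SD 0.02).
- **EDA**: subject tonic base uniform in 2–6 µS, drift 0.05 µS/min, a slow
  0.05 µS oscillation with a fixed 120 s period, +0.3 µS smoothed rise at
  full arousal; biexponential SCRs (rise 0.75 s, decay uniform 2–6 s,
  amplitudes uniform 0.1–0.6 µS) at a Poisson rate interpolating 2→8 per
  minute; noise SD 0.01 µS.
- **RSP**: sinusoid (amplitude 5%) whose rate interpolates 12→18 breaths
  per minute with small phase jitter; noise SD 0.25%.
- **Ratings**: latent clip level mapped to {3,4} (high) or {1,2} (medium),
  perturbed by ±1 with probability 0.1.

Defaults (ΔHR = +15 bpm at high arousal, SCR rate ×4, 40 subjects) are the
strong-effect recovery conditions the pipeline is validated under; the
remaining values are ordinary resting physiology for healthy adults.
Subject-level traits (tonic base, resting HR with 3 bpm between-subject SD)
are constant across a subject's two sessions — a person's skin conductance
level and resting heart rate do not reset between visits, and making them
per-session would hand window-level cross-validation a spurious
session fingerprint. For the same reason the slow tonic oscillation has a
fixed period rather than one tied to session length.

What the simulator does *not* emulate: real QRS morphology and ectopy,
respiratory sinus arrhythmia and other cardio-respiratory coupling,
motion artifacts, electrode drift and contact loss, tonic-phasic
interactions beyond additive superposition, and any systematic relation
between subjective ratings and physiology other than the injected latent
state. Passing tests therefore demonstrate that the pipeline recovers the
structure it is designed for when that structure is present and reports
chance when it is absent — not that clinical recordings would yield the
same accuracies.

Everything is driven by one seed through spawned per-subject generators;
a fixed seed reproduces a cohort byte for byte.

## Validation design

The test suite checks each stage against independent brute-force oracles
(naive-loop reimplementations of every feature formula and of kappa),
against simulator ground truth (detector sensitivity/PPV, SCR counts,
breathing-rate tracking), and end to end: a 40-subject strong-effect cohort
must reach two-level accuracy ≥ 0.85 and κ ≥ 0.6 with the six-feature set
and bagged trees, and a null-effect cohort (all arousal effects zeroed,
drift off) must sit at chance. The null check uses the clip-based
two-level labeling because its classes are balanced by construction, so the
chance level coincides with the majority share; under the subjective
labeling's structural 60/40 imbalance, fully grown trees on pure noise
score near the proportional-guessing level p² + (1−p)², which is below the
majority share itself and would conflate imbalance with signal. The
on-line path is validated by bit-exact equality of playback features with
batch features and by the 10-second event cadence.

## Known limitations

- Accuracies on simulated strong-effect cohorts are near ceiling by
  design; they validate recovery, not clinical performance.
- The causal per-window extraction is O(session × windows); for much
  longer sessions an incremental detector state would be the next step.
- QDA requires more observations per class than features; it reports an
  explicit degeneracy error instead of fitting silently.
- The playback engine emulates acquisition from completed records; true
  streaming transports (Bluetooth, sensor SDKs) are out of scope.
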