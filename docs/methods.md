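# Methods

This note records the models, conventions and numerical choices behind
`pulseaf`, and what the synthetic cohort does and does not demonstrate.

## Rhythm models

The simulator produces ground-truth beat times per one-minute record.

**NSR.** Successive RR intervals follow
`RR(t) = RR0·(1 + d·sin(2π·f_resp·t)) + ε`, with base interval
`RR0 = 60/HR`, respiratory modulation depth `d` and frequency `f_resp`, and
Gaussian jitter `ε ~ N(0, (cv·RR0)²)`. This reproduces the two salient
features of sinus rhythm for this task: low overall variability and a
narrow spectral line at the respiratory frequency in the RR tachogram.

**AF.** RR intervals are i.i.d. Gamma with the configured mean and
coefficient of variation (shape `1/cv²`, scale `RR0·cv²`). An i.i.d. draw
is the simplest serially uncorrelated ("irregularly irregular") process; we
deliberately do not model atrioventricular-node dynamics, ectopy or
fibrillatory-wave morphology. Lag-1 RR autocorrelation of generated series
is < 0.1 in magnitude.

All intervals are floored at a 0.25 s physiological refractory period.
Cohorts are balanced by construction; per-record parameters are drawn
uniformly from NSR: HR 55–90 bpm, cv 0.02–0.06, depth 0.02–0.08,
f_resp 0.15–0.35 Hz; AF: HR 70–130 bpm, cv 0.18–0.35. Record seeds derive
as `seed + index`, so any record is reproducible in isolation.

**Waveform rendering.** Each beat contributes one asymmetric pulse — a
narrow systolic lobe (Gaussian, σ = 60 ms) plus a delayed, wider diastolic
lobe (0.4 amplitude, σ = 180 ms, +150 ms) — calibrated so the combined
template has unit amplitude exactly at the beat time. Additive white
Gaussian noise (default σ = 0.02, a mild photoplethysmography-like noise
floor; the source literature does not characterize noise levels, so this is
a package convention) and sinusoidal baseline wander (default amplitude
0.1 at 0.2 Hz) are superimposed. Not emulated: motion artifacts, varying
pulse amplitude/contour, sensor saturation, ectopic beats. Consequently,
passing tests show the algorithm chain is correct and that
rhythm-irregularity features separate the two simulated classes; they do
not certify clinical performance on real recordings.

## Conditioning

Order is fixed: resample → band-pass → normalize.

- **Resampling** evaluates a degree-3 Newton divided-difference polynomial
  over the 4 input samples nearest each output instant (stencil clamped at
  the record edges). Local cubic interpolation gives O(h⁴) accuracy without
  global ill-conditioning; the operation is linear in the input.
- **Band-pass**: 4th-order Butterworth, 0.5–8 Hz, applied forward-backward
  (zero phase, length preserving). The low edge removes baseline wander,
  the high edge keeps pulse harmonics up to a ~240 bpm fundamental.
- **Normalization** divides by the 97th percentile of the filtered window's
  values, computed as the linear-interpolated order statistic (so the
  88th/97th thresholds are bit-stable and scale-invariant). Normalizing
  after band-passing means the percentile is taken on a baseline-free
  signal; normalization is idempotent and never moves a local maximum.

Defaults (100 Hz target rate, band edges, order, percentile) are all
configurable per run and logged in the run report.

## Beat detection

Candidate peaks are strict local maxima (plateaus take their first sample;
the first/last samples are excluded) whose amplitude exceeds the window's
88th percentile. A refractory rule keeps only the taller of any two
candidates closer than `min_distance` (ties: earlier). `min_distance`
defaults to 0.25 s, matching the simulator's refractory floor — a larger
merge window would delete genuine beats of fast AF records whose RR
intervals legitimately approach the floor.

**Recovery evaluation.** Detected and true beats are matched greedily
one-to-one within ±50 ms. Matching excludes a 0.5 s guard band at each
window edge: a pulse centred on the first or last instant of a window is
only half rendered and has no interior local maximum, so border beats are
unobservable for any detector. On noise-free cohorts the raw rendered
waveform is used directly (nothing to filter); interior sensitivity and
positive predictivity then exceed 99%. With noise (σ = 0.05) the full
conditioning chain is applied first and both rates stay above 95%. Dense
AF stretches lose a small fraction of peaks after band-passing because the
high-pass removes the local beat-density envelope and depresses some peaks
below the percentile threshold; this costs ~2% of beats at default noise
and does not measurably affect the downstream features.

## Features

All standard deviations use the population (÷n) convention; this choice,
the SampEn parameters and the histogram bin count are configurable.

- **SampEn**: m = 2, r = 0.2·σ of the series (the literature standard;
  tolerance inclusive, self-matches excluded; both template lengths drawn
  from the first n−m positions). A constant series has r = 0 and SampEn 0
  by the inclusive-distance convention. When no templates match (A or B
  zero) SampEn is undefined; a documented cap of 10 nats is reported with a
  warning so feature tables stay finite for model fitting. Short one-minute
  AF windows hit this cap occasionally — the cap itself is informative (it
  flags high irregularity).
- **CosEn** = SampEn + ln r − ln(mean RR). For a degenerate window
  (r = 0) it is reported as −10 (the negative cap). The constant series is
  recognized by an exact max = min test, since the floating-point std of a
  constant array is not exactly zero.
- **ShE**: 16 equal-width bins over [min, max]; degenerate range gives 0.
- **Poincaré**: SD1 = std(ΔRR)/√2, SD2 = √(2·SDRR² − SD1²) floored at 0
  before the root, ratio 0 when SD2 = 0, S = π·SD1·SD2.
- **SDRR vs STD**: both names denote the standard deviation of the IBI
  series and are reported as equal columns, mirroring the canonical
  27-name registry this package implements.
- **Tachogram**: each IBI is placed at its closing peak time and cubically
  interpolated to a uniform 4 Hz grid (order reduced below 4 intervals),
  then mean-removed. The spectrum is a one-sided boxcar FFT periodogram
  with density normalization (Parseval-exact). Band powers integrate
  half-open bins `[low, high)` — VLF 0.0033–0.04, LF 0.04–0.15,
  HF 0.15–0.4 Hz — so VLF+LF+HF equals the total-band power exactly. ULF
  is unresolvable in a 60 s window and is not extracted. MaxPeak is the
  power of the dominant in-band bin (its frequency is logged); spectral
  entropy is normalized by ln(number of in-band bins) into [0, 1];
  MeanFFT/STDFFT are statistics of in-band spectral *magnitudes* (square
  roots of the periodogram values) — magnitudes rather than powers, chosen
  once and logged.
- **Wavelet features** are computed on the conditioned waveform (not the
  tachogram): one decomposition level, Daubechies-4, periodization
  boundaries — the smallest standard orthogonal choice producing the cA/cD
  pair. With even input length this conserves energy exactly
  (Σca² + Σcd² = Σx²); odd lengths are padded by the boundary mode and
  conserve only approximately, which the statistics tolerate.

## Selection and groups

The five nested groups are fixed constants (sizes 8/11/15/20/27); the
curation step that produced them has no algorithmic definition, so the
package exposes the registry rather than re-deriving it. Rankers:
|Pearson r|, information gain (feature discretized into 10 equal-frequency
bins with ties kept together; one bin per value when ≤ 10 distinct values)
and symmetric uncertainty 2·IG/(H(feature)+H(Vt)), entropies in nats, with
lexicographic tie-breaks. The greedy wrapper adds, per step, the feature
maximizing stratified k-fold CV accuracy of a depth-3 decision tree
(configurable); ties continue (a plateau is not degradation) and a strict
decrease stops selection.

## Classification and evaluation

Default protocol: stratified 70/30 holdout with a fixed seed (optionally
stratified k-fold with pooled out-of-fold scores). Model hyperparameters
are library defaults, recorded verbatim in the run manifest. AF is the
positive class; scores ≥ 0.5 predict AF. AUC integrates the ROC curve
trapezoidally; score ties follow the standard threshold-sweep convention.
One seed controls simulation, splits and model fits, making a full
pipeline run byte-identical on rerun.

## Problem sizes

The bundled evaluation uses a 200+200-record synthetic cohort with ten
seeded holdout splits for classification, 25+25 records per condition for
beat-recovery measurement, and ≥100 random series per feature for the
oracle comparisons — sizes at which every reported rate is stable to well
under a percentage point across seeds while a complete run stays
lightweight on a single CPU.

## Known limitations

- WFDB input is not supported; signals enter as two-column CSV
  (`time_s,amplitude`). Converting PhysioNet records to CSV is left to
  external tooling.
- The simulator's class separation (NSR cv ≤ 0.06 vs AF cv ≥ 0.18) makes
  the classification task easier than clinical screening; held-out
  accuracy near 1.0 on synthetic cohorts is a pipeline-correctness check,
  not a clinical claim.
- Single-channel, fixed one-minute windows; no artifact rejection or
  signal-quality indexing.
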