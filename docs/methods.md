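# Methods

`mipower` implements a band-power analysis pipeline for two-class motor-imagery
(MI) EEG: imagined hand versus imagined feet movement. Imagined movement
modulates the sensorimotor rhythms recorded over the motor cortex — an
event-related desynchronization/synchronization (ERD/ERS) that shifts power in
the alpha (~8–12 Hz) and beta (~13–25 Hz) bands. The pipeline turns each trial
into 11 spectral features, asks three univariate rankers which features carry
the class information, and benchmarks five standard classifiers under
stratified 5-fold cross-validation, ending with a feature-ablation analysis.

## Synthetic data model

The generator produces the kind of data the analysis assumes rather than a
biophysically detailed EEG simulation. One trial on one channel is

    x(t) = sum_b  a_b · e_b(t) · cos(2π f_b t + φ_b)  +  n(t)

* one narrow-band oscillation per rhythm b ∈ {theta, alpha, beta, gamma}:
  carrier `f_b` drawn uniformly inside the rhythm's carrier range
  (theta 4–5.5, alpha 8–12, beta 13–25, gamma 26–45 Hz), random phase,
  and a slowly drifting amplitude envelope `e_b(t)` (Gaussian process
  low-passed at 0.5 Hz, depth 0.3, normalized to unit mean square so the
  waveform RMS is exactly `a_b/√2`). The theta carrier range stops at
  5.5 Hz — below the classical 7.5 Hz edge — so that theta energy stays
  inside the 3.125–6.25 Hz dyadic sub-band that measures it instead of
  leaking into the alpha band.
* `n(t)`: 1/f^γ background noise (γ = 1 by default) synthesized by spectral
  shaping of white Gaussian noise, standardized to `noise_scale` µV.

Defaults: 3 channels (C3/Cz/C4), 512 Hz, 5 s trials, 80 trials per class
(160 per "subject", mirroring a session of 8 runs × 20 trials); baseline
amplitudes theta 4, alpha 10, beta 5, gamma 2 µV; `noise_scale` 20 µV.
"Feet" trials multiply the alpha amplitude by 1.4 and the beta amplitude by
0.7 (class power therefore scales by the square: ×1.96 and ×0.49). The noise
level was set so that the default conditions put single-trial weighted-KNN
accuracy in the low-to-mid 90s — the regime of well-performing two-class MI
benchmarks — rather than at a saturated 100 %, which would make classifier
comparisons meaningless. An optional `lateralization` parameter scales alpha
on C3 versus C4 oppositely for the two classes (off by default; the 11
features aggregate channels, so lateralization adds nothing downstream).

Everything is a pure function of the config, including its seed: identical
configs produce bit-identical trial sets.

What the generator does **not** emulate: eye-blink/EMG artifacts, volume
conduction, electrode noise, inter-session nonstationarity, and heavy-tailed
outlier trials. Passing tests therefore show that the pipeline recovers
class-dependent band-power structure when it is present — not that it is
robust to real-world artifacts.

## Preprocessing

5th-order Butterworth band-pass, 0.5–100 Hz, designed in second-order
sections and applied zero-phase (forward–backward). The forward and backward
passes use steady-state initial conditions scaled by the edge sample rather
than scipy's default padded `sosfiltfilt`: with a 0.5 Hz lower edge, the
padding joint's derivative kink excites slow modes that ring through an
entire 5 s trial (a pure stop-band tone leaked 16 % RMS; with steady-state
initialization it leaks 0.3 %).

After filtering, trials are resampled (polyphase) from 512 Hz to a 200 Hz
effective rate. At 200 Hz the 5-level dyadic wavelet bands coincide exactly
with the canonical rhythm boundaries (see below); at 512 Hz they would not.
The 100 Hz upper cutoff doubles as the anti-aliasing guard. Filtering always
happens at the native rate, before resampling.

## Sub-band features

Each channel is decomposed with a 5-level db4 discrete wavelet transform
(PyWavelets, symmetric extension). Detail level j nominally covers
(fs/2^(j+1), fs/2^j); at fs = 200 Hz:

| component | band (Hz)    | rhythm          |
|-----------|--------------|-----------------|
| D1        | 50–100       | noise, discarded|
| D2        | 25–50        | gamma           |
| D3        | 12.5–25      | beta            |
| D4        | 6.25–12.5    | alpha           |
| D5        | 3.125–6.25   | theta           |
| A5        | 0–3.125      | delta, discarded|

Band signals are reconstructed by inverting the transform with all other
coefficient sets zeroed (the six single-component reconstructions sum back
to the input to ~1e−12). db4's transition bands are wide: a 10 Hz tone puts
about 80 % of its power in D4 and most of the rest in D3 — an inherent
property of the wavelet, not an implementation artifact.

Each reconstruction gets a Welch PSD with pwelch-style defaults: Hamming
window, 8 segments, 50 % overlap (segment length ⌊n/4.5⌋), one-sided
density. Per band, two scalars are taken over the in-band frequency bins
(low ≤ f < high):

* **average power** — mean PSD density (the integrated band power divided by
  a constant bandwidth factor, which cancels in the ratios);
* **varied power** — sample variance (ddof = 1) of the PSD density values
  across in-band bins, i.e. the spectral-bin reading of "variance of the
  PSD"; the alternative reading (variance of instantaneous power over time)
  was considered and rejected as inconsistent with a PSD-based definition.

The 8 avg/var quantities are averaged across channels first, then the three
relative-power features are formed from the channel-averaged band powers.
Averaging before ratios is the simplest scheme that yields 11 features from
a multichannel montage (per-channel features concatenated would give 33).
The canonical order is:

1–4 `avg_alpha, avg_beta, avg_gamma, avg_theta`;
5–7 `rel_alpha_beta, rel_alpha_gamma, rel_alpha_theta` (alpha's average
power over the other band's); 8–11 `var_alpha, var_beta, var_gamma,
var_theta`.

The ratios use an epsilon guard (denominator floored at 1e−12 µV²/Hz, with
a warning): real or synthetic EEG never has exactly zero band power, but a
degenerate input must not crash the pipeline. Under trial scaling by c, the
avg features scale as c², var features as c⁴, and the ratios are invariant.

## Feature ranking

Scores are computed from scratch (and cross-checked in the tests against
`sklearn.metrics.mutual_info_score`, `scipy.stats.chi2_contingency` and
`scipy.stats.pearsonr`):

* **Mutual information** I(F; Y) = Σ p(f,y) log[p(f,y)/(p(f)p(y))] in nats,
  between the discretized feature and the class label. Features are binned
  into equal-frequency bins (4 by default); MI and chi-square are thereby
  invariant to any strictly monotone rescaling of a feature. The base of
  the logarithm only rescales scores, not ranks.
* **Chi-square** Σ (F_O − F_E)²/F_E over the bins × classes contingency
  table, expected counts from the marginals; p-value from the χ²
  distribution with (bins−1)(classes−1) df at significance 0.05. Bins with
  expected count below 1 are merged with a neighbor (warned).
* **Correlation** Pearson r between feature pairs; pairs with |r| ≥ 0.85
  (configurable) are "highly correlated", and a greedy pass repeatedly
  takes the worst pair and discards the member with the higher mean
  absolute correlation to the remaining features (ties to the higher
  index).

Each method runs 10 iterations; every iteration scores the features on a
seeded random subsample of 80 % of the trials drawn without replacement (an
80 % draw is a subsample, not a classical bootstrap) and records ranks.
MI keeps the 6 features, and chi-square the 5 features, with the most top-k
appearances across iterations (ties broken by higher mean score); the
correlation method keeps the features that survive the discard in a
majority of iterations. Selections are reproducible from
(features, labels, method, seed).

## Classification

Five presets, all hyperparameters configurable:

| name           | model                                                       |
|----------------|-------------------------------------------------------------|
| tree           | decision tree, ≤100 splits (`max_leaf_nodes=101`)           |
| fine_knn       | 1-nearest-neighbor, Euclidean                               |
| weighted_knn   | 10 neighbors, squared-inverse-distance weights              |
| quadratic_svm  | SVC, polynomial kernel degree 2, C = 1                      |
| random_forest  | 30 bagged trees                                             |

Distance- and kernel-based models are standardized inside the CV loop
(scaler fitted on training folds only) — necessary because the features span
orders of magnitude. Folds are stratified (the balanced design makes
per-fold class balance the natural choice), seeded, and shared across
classifiers so comparisons are paired. Accuracy is pooled over held-out
folds; precision/recall/F1 are computed per class from the pooled confusion
matrix, with zero-denominator cases reported as 0 with a warning.

The quadratic SVM deliberately keeps the library's default polynomial
kernel, which is homogeneous (coef0 = 0): every term of its feature map is
even, so after standardization (which centers the classes symmetrically) a
pure mean shift is nearly invisible to it. This is the configuration whose
benchmark behavior matches the well-known weakness of untuned quadratic
SVMs on band-power features; passing `params={"coef0": 1.0}` switches to
the inhomogeneous (1 + x·y)² kernel, which is competitive with weighted KNN
on this data.

## Ablation

For each subject, weighted KNN (the strongest classifier here, as in the
benchmark that motivates the pipeline) is evaluated on: all 11 features;
all except the relative-power ratios {5,6,7}; the MI top-6; the chi-square
top-5; and the correlation survivors. Loss in accuracy is defined as
`accuracy_all − accuracy_subset` in percentage points and may be negative
(a subset can beat the full set). The identity holds exactly in every
emitted report. "Subjects" are realized as independent synthetic sessions
differing by seed.

## Numerical choices and degenerate inputs

* Welch parameters are recorded in every `PSDEstimate`; segment length
  never exceeds the signal.
* A constant feature yields MI 0 (warned), a degenerate chi-square table
  scores 0 with p = 1, and a constant column's correlations are set to 0
  (warned); `correlation_coefficient` itself refuses constant inputs.
* Rank ties within an iteration break by feature order; selection ties by
  higher mean score.
* `resample_to_effective` refuses to upsample; equal rates return a copy.
* Signals shorter than (filter_length − 1)·2^levels are rejected by the
  DWT with the minimum length in the message.

## Problem sizes

The shipped analysis and the test suite run 10 synthetic subjects × 160
trials (plus 3 null subjects with no class effect), 5-fold CV, 10 ranking
iterations — a desk-scale analogue of the 10-subject benchmark design the
pipeline mirrors. A full run of the five analysis stages takes on the order
of a minute on one CPU.

## Known limitations

* Channel aggregation discards spatial information; with `lateralization`
  enabled the generator produces C3/C4 asymmetries the features cannot see.
* db4's wide transition bands mix neighboring rhythms by design; band
  "edges" are nominal.
* The equal-frequency binning MI/chi-square estimators are plug-in
  estimators with small positive bias at small n; scores are comparable
  across features (same n, same bins), which is all ranking needs.
* EDF support is interoperability-grade: one file per trial plus a JSON
  sidecar, 16-bit quantization on export; run-level annotation-based
  epoching is not implemented.
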