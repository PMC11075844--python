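# Methods

`emgbicoh` implements a diagnostic pipeline for surface EMG of the
knee-spanning muscles: condition the signal, quantify quadratic phase
coupling with bicoherence maps, render the maps as fixed-size images, and
classify them as Normal vs. knee-osteoarthritis (KOA) with a compact
convolutional network under a repeated random-subsampling protocol. This
note records the models, the parameters that matter, and the design
choices made where more than one defensible option existed.

## Signal model and synthetic cohorts

Real clinical EMG is not distributed with the package; the synthetic
generator exists so that every stage can be tested against a known ground
truth. A generated signal is a sum of three cosines at f1, f2 and f1+f2
(defaults 80, 140, 220 Hz — inside the 30–300 Hz EMG band and away from
the 60 Hz notch), with phases redrawn per block:

    x(t) = e(t) · [a1 cos(2π f1 t + φ1) + a2 cos(2π f2 t + φ2)
                   + a3 cos(2π (f1+f2) t + φ3)] + w(t)

Per block, φ1 and φ2 are independent Uniform(0, 2π); with probability λ
("coupling") φ3 = φ1 + φ2, otherwise φ3 is an independent uniform draw.
Bicoherence at (f1, f2) converges to λ as segments accumulate, giving
analytic expectations: λ=1 → 1, λ=0 → 0. Phases are redrawn every
`block_len` samples (default: the estimator's segment length) so that the
segment-averaging assumption of the estimator holds.

A cohort emulates a 20-subject gait study: 10 subjects per class, five 5 s
walking trials each, five muscles (BF, MG, RF, ST, VM), fs = 1500 Hz. The
two classes differ only in coupling: Normal λ=0.2, KOA λ=0.9, both with
10 dB additive white Gaussian noise and a 1 Hz raised-cosine burst envelope
standing in for gait cycles (~1 stride/s). Subjects get seeded jitter of
±5% on amplitudes and ±2 Hz on frequencies so they are distinguishable
without destroying class structure. Trial length is one steady walkway
pass (~5 gait cycles). What the generator does *not* emulate: motor-unit
recruitment, crosstalk between electrodes, non-stationarity across a
session, or any claim about the actual spectral structure of KOA gait EMG
— the λ values are stand-ins that make the pipeline testable, so a passing
end-to-end test demonstrates that the pipeline detects coupling
differences, not that real KOA produces them at these levels.

## Preprocessing

The filter chain is the standard gait-EMG recipe: a 30–300 Hz sixth-order
Butterworth band-pass (realized as second-order sections; a band-pass of
order 2N comes from N analogue pole pairs, so `butter(3, ...)`), a 60 Hz
second-order IIR notch (Q = 30, i.e. 2 Hz bandwidth — no bandwidth is
standard, this pins one), and full-wave rectification. Filters run
forward–backward by default (zero phase): phase distortion would corrupt
exactly the phase relationships the next stage measures. Zero-phase
application squares the magnitude response, so stated single-pass
attenuations double (the 30/300 Hz corners sit at −3 dB single-pass,
−6 dB effective; 10 Hz is ~−31 dB single-pass, ~−62 dB effective).
Rectification comes last, after both filters; low-frequency artifact
removal is handled by the 30 Hz corner rather than a separate high-pass.

## Bicoherence estimation

The direct method: split the record into `seg_len`-sample segments with
fractional overlap, subtract each segment's mean, apply a Hann window,
FFT to `nfft` points, and average the triple products across the K
segments:

    b(f1,f2)   = (1/K) Σ_k X_k(f1) X_k(f2) X_k*(f1+f2)
    p12(f1,f2) = (1/K) Σ_k |X_k(f1) X_k(f2)|²
    p3(f1,f2)  = (1/K) Σ_k |X_k(f1+f2)|²

    bic(f1,f2) = |b| / sqrt(p12 · p3)

This is the normalization used by the classic MATLAB higher-order spectra
toolbox's `bicoher`: by the Cauchy–Schwarz inequality over segments it is
bounded in [0, 1] regardless of the signal, equals 1 under full phase
coupling, and decays as 1/sqrt(K) for independent phases. Index
arithmetic runs on the full nfft grid with wrap-around; maps are
symmetric in (f1, f2) by construction and are displayed with centered
(−fs/2, fs/2) axes. Bins whose denominator falls below 1e-12 times the
maximum denominator are masked (reported as 0 with `mask=False`) to avoid
0/0 at empty bins. A deliberately naive triple-loop estimator with its own
DFT serves as an independent oracle; the vectorized path must agree with
it to 1e-10 relative on small inputs.

**Resolution vs. variance.** Defaults are nfft = seg_len = 128 with 50%
overlap: at 1500 Hz this gives 11.7 Hz bins and ~115 segments per 5 s
trial. The choice is deliberate: per-trial coupling estimates are limited
by estimator variance (∝ 1/sqrt(K)), not by frequency resolution — the
class signal is coupling *strength* at a known coarse location, and
measurements during development showed the between-class separation of
the coupled-bin statistic roughly doubling when moving from 512-sample to
128-sample segments on 5 s records. Analyses of longer records that need
finer bins can raise `nfft`/`seg_len` freely; the unit tests for coupling
detection use 512 where bin placement matters.

The "ALL muscles" condition averages the five per-muscle maps of a trial
element-wise (masks conjoined) before rendering — one of several readings
of averaging across muscles; map-space averaging preserves the [0, 1]
scale and commutes with rendering.

## Imaging

Maps are rendered as dense 224×224×3 heatmaps: values clipped to a fixed
[0, 1] range (never per-image normalized, which would erase absolute
coupling differences between classes), passed through a pinned colormap
(viridis), nearest-neighbor resampled (no invented inter-bin values), and
stored as lossless PNG. Labels live in a manifest, never in pixels; a
test renders one map under both class labels and compares bytes. A
decorated mode (axes, colorbar) exists for figure making but is not used
for classifier input.

## Classification

The default backbone is a compact CNN implemented directly on NumPy
(im2col convolutions, explicit backward passes) so that training is
exactly reproducible from a seed: three 3×3 convolution–ReLU–2×2 max-pool
blocks (8/16/32 channels), then a dense softmax readout on the flattened
final feature map. Design choices that matter for this image family:

- **Input reduction 224 → 56 by max pooling.** The class signal is a
  small set of bright bins; averaging would dilute them 16-fold, max
  pooling preserves them.
- **Flattened readout, not global pooling.** The informative bins sit at
  *fixed* bifrequency positions; global pooling is translation invariant
  and wipes out exactly that information.
- **Training-mean centering.** The constant heatmap background otherwise
  dominates early gradients.
- **Model selection on balanced validation accuracy.** With subject-level
  15% validation splits of a 20-subject cohort, the validation set is
  2:1 class-imbalanced, and plain accuracy rewards single-class collapse.
  The best-on-validation snapshot (ties broken by validation loss) is
  restored after training.
- **Decoupled weight decay (5e-4) on weight matrices and cosine learning-
  rate decay.** The dense readout sees only ~14 training subjects and
  will otherwise memorize subject-specific pixels.

Optimization follows the study protocol: Adam, initial learning rate
0.001, minibatch 32, up to 60 epochs, three validation evaluations per
epoch. Early stopping is off by default (small validation sets plateau
too noisily to stop on). An external scikit-learn-compatible classifier
can replace the backbone.

## Evaluation protocol

The image set is split 70/15/15 into train/validation/test, five times
with fresh randomization (repeated random subsampling), stratified by
class. Splitting defaults to the *subject* level — class is a property of
the subject, and image-level splits would leak subject identity between
train and test; image-level mode is retained for protocol comparison.
Partition sizes are exact up to rounding globally (greedy
largest-remainder allocation that respects class totals). Per run, the
confusion matrix (each class taken as positive in turn) yields accuracy,
precision, sensitivity, specificity, F-measure, MCC and AUC (rank-based,
tie-corrected, computed from held-out scores); ratios with zero
denominator are reported as NaN, never coerced to 0. Across runs, metrics
are summarized as mean ± sample (n−1) standard deviation. Muscle groups
are compared with one-way ANOVA on per-run values plus Tukey's HSD at
α = 0.05 (scipy / statsmodels).

## Problem sizes and determinism

The shipped tests and the acceptance script run the full default cohort
(500 records, 600 images including the ALL group, five training runs) in
minutes on one CPU; estimator verification uses 16–512-point FFTs as
appropriate for each property. All randomness flows from explicit seeds
through `numpy.random.SeedSequence`; a fixed seed reproduces cohorts
bit-exactly and training runs exactly on the same platform.

## Known limitations

- The generator's QPC construction is a test harness, not EMG physiology;
  absolute accuracies on synthetic cohorts say nothing about clinical
  performance.
- Bicoherence here is auto-bicoherence per muscle; cross-muscle coupling
  is out of scope.
- Rectification (a nonlinearity) is applied before spectral analysis per
  the study protocol; it measurably raises the bicoherence floor of both
  classes. The class contrast survives, but analyses caring about
  absolute coupling levels should disable it.
- The compact CNN is a desk-scale stand-in for a large pretrained
  backbone; no transfer learning is included.
- With 20 subjects, subject-level test sets hold three subjects; per-run
  metrics are correspondingly coarse (steps of 1/75 on accuracy).
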