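# Methods

`nirstack` decodes two-class motor activity (task vs rest) from functional
near-infrared spectroscopy (fNIRS) recordings. This note documents the
models and procedures the package implements, the assumptions behind them,
and the choices made where the design was genuinely open.

## Signal model and preprocessing

Raw data are dual-wavelength light intensities `I(t; λ)` per source–detector
channel. The chain to hemoglobin concentration changes is:

1. **Absorbance change.** `ΔA(t; λ) = −log10(I(t; λ) / Ī(λ))`, with `Ī`
   the mean intensity over a baseline window (default: the initial 30 s
   rest block). Choosing the baseline fixes the reference point of all
   concentration changes; they are *changes*, never absolute levels.
2. **Modified Beer–Lambert law.** Per channel and sample,

       [ΔC_HbO; ΔC_HbR] = A⁻¹ · [ΔA(λ₁); ΔA(λ₂)] / (l · d)

   where `A` is the 2×2 extinction-coefficient matrix in µM⁻¹·cm⁻¹, `l`
   the source–detector separation (3 cm) and `d` the differential path
   length factor. Total hemoglobin is `ΔC_HbT = ΔC_HbO + ΔC_HbR`, an
   invariant enforced after every stage. The default coefficient table is
   for the 760/850 nm pair (compiled hemoglobin spectra) with `d = 6.0`;
   both are instrument constants, fully overridable, and the conversion
   refuses extinction matrices with condition number above 1e8.
3. **Bandpass.** 3rd-order Butterworth, 0.01–0.2 Hz, applied
   forward–backward (zero phase) so event timing survives for epoching.
   The band keeps the hemodynamic response and Mayer waves while removing
   drift (below 0.01 Hz), respiration (~0.3 Hz) and cardiac pulsation
   (~1 Hz). Measured on the pipeline's own response: 0.1 Hz passes with
   gain ≈ 0.99, 1.0 Hz is attenuated to ≈ 1% RMS.
4. **Baseline correction.** Mean subtraction over the union of the initial
   and final 30 s rest windows — the simplest reading of rest-window
   baseline correction; after it those windows average to zero exactly.

## Task paradigm and epoching

The block design is 30 s rest, then 10 trials of 10 s task + 20 s rest,
then 30 s rest (360 s total; 300 s excluding the padding).

Windows are placed and labeled on the **continuous-time schedule in
seconds**, where the block arithmetic is exact; samples enter only when a
window's content is extracted (`start = round(start_s · fs)`, fixed length
`round(window_s · fs)`). At the non-integer rate of 10.1725 Hz any
sample-anchored grid drifts against the block boundaries, so a
seconds-anchored grid is the only scheme under which a window can be
*exactly* one task block. A window is labeled task if at least `purity`
(default 0.8) of its interval overlaps a task block delayed by
`label_shift_s` (default 2 s, compensating hemodynamic lag), rest if at
least `purity` lies outside all task blocks, and is discarded otherwise.

Defaults: 3 s windows, **3 s stride (non-overlapping)**, HbO only.
Overlapping strides are supported but not the default: with stride <
window, epoch-level train/test splitting places windows that share
samples on both sides of the split, so a model can score well by
memorizing overlapping content rather than decoding the task — the
evaluation stops measuring the class signal. A non-overlapping stride
removes the leak;
users who want more samples per subject can lower the stride knowingly.
Splits are stratified and epoch-level, 80/20 by default, deterministic
under a seed.

## Feature extractors

Three small networks classify epochs and donate their 32-unit penultimate
dense layer as a feature map:

- **1D-CNN** — two 1D convolutions over time (64 filters, kernel 2, ReLU),
- **LSTM** — two stacked 64-unit LSTM layers returning sequences,
- **Bi-LSTM** — the bidirectional variant (64 units per direction, 128 per
  step),

each followed by the shared tail: max-pool 2 over time, batch
normalization, flatten, dropout 0.2, dense 32 (ReLU), dense 2. Epochs
enter the networks time-first — sequence length = window samples, one
input feature per fNIRS channel per step — the standard layout for
multichannel biosignals. Training is Adam (learning rate 1e-4), batch 32,
categorical cross-entropy, with optional early stopping (patience on
validation loss, best weights restored). The output layer is linear with
softmax folded into the loss; a literal ReLU output mode exists behind
`output_activation="relu"` for fidelity experiments, but ReLU-then-softmax
is numerically fragile and not the default. Feature extraction always runs
in inference mode (dropout off, batch-norm statistics frozen), so repeated
extraction is bitwise identical.

The networks are trained by the package's own numpy backend
(`nirstack.nn`): explicit backpropagation, including through time for the
recurrent layers, with every layer's analytic gradient verified against
central finite differences in the test suite. Pure numpy makes training
bit-reproducible under a seed on any platform.

## Fusion and the two proposed classifiers

The three 32-vectors are concatenated in fixed order [cnn | lstm | bilstm]
into a 96-vector. Two routes classify it:

- **stack** — a dense 64→64→2 network (ReLU, same training regime) on the
  96 features. This is direct training on concatenated features, not
  classical stacked generalization on held-out base-model predictions.
- **fft** — a real-input DFT along the 96 feature positions; the 49
  non-negative-frequency magnitudes feed the same dense network. Options
  keep all 96 magnitude bins or append phases for ablation. Worth knowing:
  dropping phase makes the transform non-invertible, so the magnitude
  spectrum can discard class information; the ablation flags exist to
  measure that on a given dataset.

Per-feature z-scoring, fit on training rows only, precedes the dense
network by default; without it the heterogeneous scales of DFT bins
dominate early training. The dense heads get a larger epoch budget than
the extractors (default 300 with patience 30): with ~25 training batches
per epoch at typical cohort sizes they are otherwise stopped long before
convergence, which is a training artifact rather than a property of the
method. Predicted labels map to prosthesis commands as task → hand-close,
rest → hand-open; no hardware I/O is performed.

## Evaluation

The positive class is task (activity). Confusion matrices are ordered
[activity, rest]; accuracy is reported in percent, F1 from
precision/recall with zero-denominator cases returning 0 by convention.
Processing is per subject; per-method aggregates are mean ± sample (n−1)
standard deviation. Method comparisons use a paired two-sided t-test
across subjects (Wilcoxon signed-rank optional) at a Bonferroni-corrected
threshold `alpha / n_comparisons` (0.05/4 = 0.0125 for one proposed method
against four alternatives). Zero-variance paired differences are reported
as non-significant (p = 1) rather than an error.

A reference table of published subject-wise accuracies for the original
20-participant hand-gripping study ships as package data
(`reference_subject_accuracies.csv`); it exercises the aggregate and
comparison plumbing against real printed numbers and reproduces its
printed per-method averages within rounding.

## Synthetic data generator

The generator stands in for the private study recordings: 20 channels at
10.1725 Hz over the motor-cortex montage, the 360 s paradigm above, and a
forward Beer–Lambert model (`I = I₀·10^(−A·ΔC·l·d)`) that is the exact
inverse of the converter, so simulated concentrations survive a round trip
to ≤1e−8 relative error.

Task-evoked ΔHbO is a boxcar convolved with a unit-peak double-gamma HRF
(peak 6 s, undershoot 16 s), scaled by `activation_amp_uM` on a subset of
channels (default half), with ΔHbR at −0.35 of ΔHbO. Per-trial response
gains vary (lognormal-like, sd 0.3) to mimic attention/habituation.
Physiological confounds — cardiac (1.0 Hz), respiration (0.3 Hz), Mayer
waves (0.1 Hz) — are **spatially coherent**: one global phase per
component and subject with mild per-channel amplitude and phase jitter,
because systemic physiology is shared across channels in real data and
per-channel-independent phases would let channel averaging cancel it.
White sensor noise and a slow random-walk drift are per-channel. Default
amplitudes (activation 0.06 µM; Mayer 0.5, white 0.8, drift 0.5,
between-subject sd 0.02 µM) put single-network decoding in a challenging
but clearly-above-chance regime, which is what the real recordings of this
kind exhibit. Subject seeds derive deterministically from one master seed;
identical seeds give byte-identical arrays.

What the generator does *not* emulate: motion artifacts, optode-coupling
changes, task-correlated systemic physiology (scalp blood flow responding
to effort), spatially structured activation patterns, and non-stationary
noise spectra. Passing tests on synthetic cohorts therefore demonstrate
that the pipeline's machinery is correct and well-behaved, not that the
reported real-data accuracies transfer.

## Problem sizes and numerical choices

Cohort-level runs in the test suite and the acceptance script use 20
simulated subjects with extractor training capped at 30 epochs (patience
6); that is where their learning curves flatten on the synthetic cohorts,
and the library default remains 100 epochs with patience 10. Degenerate
inputs fail loudly: non-positive intensities, singular extinction
matrices, series shorter than the filter warm-up, single-class training
sets, non-finite losses (raised as `TrainingDivergedError`), and feature
width mismatches all raise typed errors with the offending quantity named.

## Known limitations

- The numpy backend is CPU-only and single-threaded beyond BLAS; it is
  sized for 20-channel, few-hundred-epoch problems, not large cohorts.
- Magnitude-only FFT features discard phase; whether that costs accuracy
  depends on where the class information lives (ablation flags provided).
- Sliding-window decoding with overlapping strides leaks information
  across epoch-level splits; the default avoids it, but the option exists.
- The montage ships approximate 2D coordinates for plotting only; no
  spatial modeling uses them.
- SNIRF support is read-only and minimal (continuous-wave intensities,
  first two wavelengths).
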