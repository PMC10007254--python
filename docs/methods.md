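# Methods

This note records the modeling choices behind `crossphys`: the processing
chain, the two network architectures, what the synthetic generators emulate
(and deliberately do not), the numerical conventions of the training engine,
and the limitations of desk-scale validation.

## Processing chains

**Seizure experiment.** Per recording: (1) per-channel linear detrend (least
squares, removes mean, offset and slow drift); (2) 0.5–50 Hz Butterworth
bandpass, applied forward–backward so the filter is zero-phase and labels
stay sample-aligned; (3) global field power over the 29 channels — the
across-channel standard deviation at each sample (population 1/N
normalization). GFP is computed per sample index; the clock unit is
irrelevant to the formula. The GFP trace is cut into 10-s windows with 8-s
overlap (step 2 s, `floor((L−w)/step)+1` windows), and each window is labeled
by strict containment in one state interval:

* interictal — after the previous seizure (onset + configurable seizure
  duration, default 0) and at least 50 min before the next onset;
* preictal 40–30 / 30–20 / 20–10 — the three 10-min bands ending 30, 20 and
  10 min before an onset, half-open `[T−2400, T−1800)` etc., clipped to the
  recording.

Windows that straddle any boundary are dropped rather than majority-labeled:
with a 2-s step the information lost is small and label noise is avoided.
The stretch after the final onset is post-ictal, not interictal, and is
excluded by default (`include_tail` reverses this). Onsets closer than
40 min to the recording start yield truncated bands and a warning flag on
the recording, not an error. Per-state counts are then equalized by seeded
undersampling without replacement, because the study design uses exactly
balanced states; the count per state is a configuration input (desk default
200, published scale 12 222).

**Sleep experiment.** EEG (Fpz-Cz, 100 Hz): detrend, then 30-Hz Butterworth
lowpass. ECG (256 Hz): detrend, 0.5–40 Hz bandpass, then polyphase
resampling to 100 Hz so a 30-s epoch occupies exactly the model's
3000-sample input grid — transfer requires an identical input shape, and
downsampling the richer signal is the information-preserving direction.
Both are cut with 30-s windows and 22.5-s overlap (step 7.5 s) and labeled
from the hypnogram: a window keeps a stage only if it lies entirely within a
run of identically scored 30-s epochs. R&K scores map onto the five-stage
standard (W→W, S1→N1, S2→N2, S3/S4→N3, REM→REM; movement/unknown epochs are
dropped). Detrending and filtering are applied per recording before
windowing, so overlapping windows see identical samples.

The bandpass/lowpass default order is 8 (a Butterworth applied twice is
zero-phase with a squared magnitude response). Order 8 keeps in-band rhythms
within 1% while attenuating a 60-Hz mains tone below 5% RMS through the
0.5–50 Hz band; a 4th-order filter leaves ~19% of the tone, which is too
leaky for the seizure band structure. The order is a `FilterSpec` field.

## Architectures and engine

Both CNNs are declared as ordered layer lists from which everything is
derived. Convolutions and poolings are valid (unpadded) with
`out = floor((in − k)/s) + 1`; this is the unique padding convention that
reproduces the published per-layer output lengths (2556, 2554, 1273, …;
2996, 1496, 744, …). Two printed entries are internally inconsistent and are
corrected by arithmetic: the second seizure conv outputs 64 channels (its
filter count), and the second sleep conv outputs length 2992 = 2996 − 5 + 1
(confirmed by the downstream pooled length 1496).

Hidden activations are rectified-linear, applied after a convolution's batch
norm (or after the conv itself if no BN follows) and after hidden dense
layers; the head is softmax with cross-entropy. Initialization is He-scaled
Gaussian from a seeded generator, so identical seeds give bit-identical
networks. The engine is pure numpy: convolutions are evaluated as BLAS
matrix products over an im2col expansion, with activations kept channels-last
``(batch, length, channels)`` so the expansion copies contiguous channel
vectors; batch norm uses momentum-0.1 running statistics and ε = 1e-5; all
tensors are float32. On one CPU a 128-window training batch costs ≈ 4 s
(seizure model) / ≈ 1.8 s (sleep model).

Training follows the published settings: Adam, batch 128, learning rate
2×10⁻⁴ (seizure) or 10⁻³ (sleep), reduced on validation-loss plateau down to
10⁻⁵ / 10⁻⁴. Reduce-on-plateau factor (0.5) and patience (5 epochs) are not
published; common defaults are used and both are configurable. Early
stopping (patience 10 on validation loss) is on by default for the sleep
experiment only, where it is part of the protocol; maximum epochs default to
100 at full scale and 20 at desk scale. The best-validation-loss weights are
restored after training. Benchmark runs may set `stop_at_val_accuracy` to
halt as soon as a target accuracy is reached. The learning rate never drops
below `min_lr`; non-finite loss raises with the epoch index.

**Freezing.** `first_n_layers` counts over the 12 ordered feature layers of
the seizure model (four conv–BN–pool stages), so the studied depths
{3, 6, 9, 12} land exactly on stage boundaries; `named_blocks` freezes a
contiguous prefix of the sleep model's blocks. Frozen layers are excluded
from gradient updates — their parameters are bit-identical after any amount
of fine-tuning, asserted at runtime — and frozen batch-norm layers run in
inference mode on their stored source statistics: fixed weights should not
be silently re-scaled by a shifted target distribution. Re-estimating the
statistics on the target domain is available (`bn_mode="reestimate"`) but is
not the default. Backpropagation stops below the deepest trainable layer,
which is why heavily frozen fine-tuning is fast. Model selection across CV
folds uses the best mean validation accuracy.

## Synthetic data: what it emulates, what it does not

The generators exist so every pipeline stage is testable without
multi-gigabyte downloads; their parameters are fixed design choices, not
fitted quantities.

* **Seizure EEG** — 29 channels, 512 Hz. Interictal background: 1/f
  ("pink") noise, unit variance per channel, plus 10% white noise. Each
  preictal band adds a sinusoid at a band-specific frequency (4, 8, 16 Hz
  for 40–30, 30–20, 20–10) at 3 dB tone-to-background power, projected
  through a random zero-mean unit-RMS channel topography. The zero-mean
  ("dipolar") topography matters: GFP removes any common-mode component, so
  a signal added equally to all channels would vanish; a topography with
  both polarities survives as across-channel variance, which is also how
  real focal activity appears in GFP.
* **Sleep EEG** — per-epoch stage rhythms on a pink background at 3 dB:
  W 8–12 Hz; N1 4–7 Hz; N2 4–7 Hz plus 1-s 12–14 Hz spindle bursts every
  ~3 s; N3 0.5–2 Hz at 3× amplitude; REM two 4–8 Hz tones at 0.6×
  amplitude.
* **Sleep ECG** — a schematic P–QRS–T template train (R amplitude 1) whose
  rate and variability depend on stage: W 75±5, N1 70±4, N2 65±3, N3 58±2,
  REM 72±8 beats/min, plus respiratory sinus arrhythmia at 0.25 Hz with
  depth tied to the stage's variability, and broadband noise of standard
  deviation 0.15 (set to 0 for noiseless oracle tests).
* **Hypnograms** — a first-order Markov chain over the five stages with a
  diagonally dominant transition matrix (diagonal 0.60–0.80, plausible
  successors elsewhere); sequences of ≥ 50 epochs are redrawn with derived
  seeds until all five stages appear, which leaves the empirical transition
  frequencies within ±0.05 of the matrix at n = 10 000.

All generators are bit-deterministic given the scenario seed. Deliberately
absent: artifacts (blink, EMG, electrode pops), non-stationary drift between
nights and subjects, inter-patient variability in rhythm frequencies, and
any physiological coupling between stages beyond the Markov chain. Passing
tests on this data therefore demonstrate that the *pipeline and protocol*
are correct and that the networks can learn genuinely class-linked spectral
and rhythm structure at desk scale — they say nothing about accuracy on real
cohorts, which is why published real-data performance figures are not
reproduction targets here.

A consequence worth stating: at desk scale (200 windows per state) the
synthetic EEG sleep task is easy (≥ 85–95% validation accuracy within 20
epochs) while the ECG task is hard (~55–60% with the full desk training
set) —
heart-rate distributions of adjacent stages overlap, which mirrors the real
EEG-over-ECG advantage. The transfer benchmark therefore measures a
*directional* claim: with the ECG training set cut to 10% (~80 windows,
less than one batch), fine-tuning the EEG-pretrained model with block_1
frozen is on average at least as accurate as training from scratch on the
same windows. Because 20 epochs would mean only ~20 gradient steps at that
size, both arms of this comparison get the same enlarged budget (60 epochs,
early stopping patience 10); everything else is identical between arms.

## Numerical conventions and degenerate cases

* Intervals are half-open `[start, end)` seconds; samples are 0-based.
* GFP of a constant-across-channels signal is exactly zero; GFP requires
  ≥ 2 channels.
* Detrending a constant channel yields zeros; detrend is idempotent.
* A signal shorter than one window yields an empty window list, not an
  error; a state with zero windows is an error naming the state.
* Metric denominators of zero (no positives, chance agreement p_e = 1)
  yield an explicit undefined marker, never a silent 0.
* Repeat aggregation uses the sample standard deviation (n−1); a single
  repeat reports std 0 with a flag.
* The EDF writer emits plain 16-bit EDF (integer sampling rates, 1-s
  records, physical unit µV); round trips are exact to the 16-bit
  quantization step. Annotations travel in a two-column text dialect
  (`onset<TAB>stage`, END sentinel) rather than embedded EDF+ annotations.

## Problem sizes

Default (desk) scale: 200 windows per state, ≤ 20 training epochs, single
train/validation split; a full synthetic run of either experiment takes
minutes on one CPU. The published cohort sizes (12 222 / 16 000 windows per
state, 10-/5-fold cross-validation, 5/10 repeats, 100 epochs) are reachable
through the same configuration surface (`windows_per_state`, `k_folds`,
`repeats`, `hyper`) given correspondingly more compute.

## Known limitations

* No GPU path; the numpy engine is single-process and CPU-bound.
* The EDF reader handles what the four public datasets and the fixtures
  need, not the full EDF+ specification.
* `exp1` subjectwise/patient-specific synthetic mode emulates the
  two-corpus design with two generated "datasets" of one subject each;
  multi-subject synthetic cohorts require composing epoch sets manually.
* Hyperparameter search, recurrent/temporal context models, and
  artifact simulation are out of scope.
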