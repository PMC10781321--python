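# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the package's tests demonstrate.

## The decoding model

### Encoder

The encoder treats time as the recurrence axis and the four electrodes
(TP9, AF7, AF8, TP10) as a convolutional spatial axis. At each time step
the convolutional LSTM applies a kernel-2, valid-padding convolution over
the electrode axis (4 → 3 positions) for each of its 20 filters; the
recurrent convolution is 'same'-padded so the hidden state stays 3 x 20.
This layout is forced by dimension arithmetic: only a spatial extent of 4
with kernel 2 and no padding yields a 3 x 20 final state, and a stride-1,
no-padding transposed convolution with a 14 x 2 kernel is the only setting
mapping 3 x 20 to the 16 x 21 latent image.

**Gate-bias initialization (chrono).** Forget-gate biases are drawn per
filter as log U(1, T_max) with T_max = 512 samples (the record length);
input-gate biases are their negatives; all other biases are zero and
weights are Glorot-uniform. This spreads the cells' integration timescales
log-uniformly from one sample up to the whole record. The long-timescale
cells accumulate energy-like statistics of the signal over the full trial,
which is what makes the final hidden state carry band-power information;
with near-zero biases the cell memory is a few samples and the final state
is essentially a snapshot of the last milliseconds — informative about
instantaneous phase (which is random across trials) and nothing else.

### Decoder

The decoder is scaffolding used only to train the encoder. The flattened
latent image is read as a 336-step sequence by a 2-unit LSTM (returning the
full output sequence, so the latent content is not bottlenecked through two
numbers); then, in order: a convolution (3 filters, extent 4), two
stride-1 transposed convolutions (3 filters, extent 3), three convolutions
(7 filters, extents 90, 90 and 11), and a final convolution (4 filters —
one per electrode — extent 10), all 1-D along the sequence axis with tanh
between layers and a linear last layer. These valid/full convolutions turn
336 steps into 140; a fixed (non-learned) linear-interpolation matrix
stretches the 140-step, 4-channel output to the 4 x S target. The layer
stack as printed does not dimension-check on its own; the interpolation
adapter is this package's resolution, chosen so the autoencoder contract —
matching input/output shapes and decreasing reconstruction loss — holds for
any S ≥ 110.

### Training

Mean (not sum) squared reconstruction error, so the loss is invariant to
dataset size; Adam with learning rate 1e-3, batch 16, 30 epochs by default;
weight init and batch shuffling from one seed. Labels are never used.
Non-finite loss raises a divergence error naming the epoch. Bit-exact
reproducibility assumes single-threaded execution. The networks run on a
small reverse-mode autodiff engine (`fogbci._autodiff`) whose gradients are
finite-difference-checked in the test suite.

## Signal conditioning

Band-pass 0.5-40 Hz, Butterworth order 4, applied forward-backward
(zero-phase), covering delta through beta while rejecting drift and line
noise; optional mains notch. Records shorter than 3 x order samples are
rejected.

**Amplitude conditioning.** The default divides all channels by one fixed
global scale (10 µV per unit, the order of resting EEG RMS), keeping
network inputs O(1) while preserving each trial's amplitude structure. A
per-record, per-channel standardization (zero mean, unit variance, with
stored factors for exact inversion) is available but is *not* the default
in the decoding pipeline: ERD/ERS class signatures are band-power — i.e.
amplitude — modulations, and normalizing every channel of every trial to
unit variance removes precisely that signal. This was verified empirically:
with per-record standardization the end-to-end benchmark decodes at chance;
with global scaling it reaches ≥ 0.95 accuracy under the default
conditions.

## The synthetic generator

Each trial is, per channel: pink noise (1/f, RMS 0.7 on the generator's
internal scale) plus three-sinusoid mixtures in theta (4-8 Hz), alpha
(8-13 Hz) and beta (13-30 Hz), with baseline RMS 0.35 / 0.45 / 0.4
respectively and random phases per channel. Class profiles multiply band
amplitudes (ERS > 1, ERD < 1): RX boosts alpha 2x everywhere; LH halves
alpha and boosts beta 1.5x on AF7/TP9; LF boosts beta 2x on AF8/TP10; MA
boosts theta 2x and beta 1.5x on AF7/AF8. A `separation` parameter scales
all contrasts (effective gain = 1 + separation x (profile - 1)); at 0 the
classes are statistically identical. The signal is scaled to microvolts
(base amplitude 50 µV → RMS ≈ 10 µV) and hard-limited at twice the base
amplitude so samples respect the physiological 100 µV ceiling.

Numerical choices worth knowing:

* Sinusoid frequencies are drawn uniformly *from the record's Fourier grid*
  (k / T) without replacement, not from the continuous band. Grid tones are
  leakage-free, so each class's boosted band dominates the periodogram
  reliably; with continuous draws, spectral leakage, scalloping and
  near-coincident components blur the intended band structure. The binding
  calibration constraint is MA, whose 2x theta boost must dominate its own
  1.5x beta boost while LH's 1.5x beta must dominate the theta baseline —
  capping the achievable power ratio at 2, hence the need to remove every
  other source of spectral variance.
* Each record draws from its own child of the dataset seed, so record i is
  reproducible in isolation and label assignment (round-robin, balanced to
  within one) is independent of the noise draws.

**What the generator does not emulate:** eye-blink/EMG artifacts, volume
conduction and realistic scalp topographies, non-stationarity within a
trial, inter-subject variability, and line noise. Tests passing on this
generator therefore show that the pipeline recovers band-power class
structure under clean conditions; they do not establish performance on
real recordings, where the published headline numbers for this family of
methods come from data that is not publicly retrievable.

## Classification benchmark

All classifiers are scikit-learn estimators with the reference settings
(RF 250 trees; SVC C = 1.0, RBF; GB 159 estimators, depth 4; DT Gini,
unlimited depth) and library defaults elsewhere. One stratified 80/20 split
per split-seed is shared by all algorithms; stratification keeps every
class in both folds at n = 200 (the spec of a plain 80/20 split would
otherwise occasionally drop a class from the 40-trial test fold). Metrics
are computed from the confusion matrix by definition; zero-denominator
cases report 0 with a logged warning. The latent image flattens row-major
to 336 features, and the importance map un-flattens with the same
convention — the pair is round-trip tested.

## Fog latency simulation

Single-server FIFO nodes, links as pure delay pipes (propagation +
size/bandwidth), event-driven with a time-ordered heap. Default topology:
fog node 2 ms from sensor and actuator, cloud 50 ms, bandwidth 1e4 bits/ms,
10^4-bit messages (one EEG window), both processors at 5 ms service, 1000
messages with exponential inter-arrivals of mean 20 ms. With equal compute
the fog advantage comes from proximity alone; the ordering is
parameter-dependent and inverts when the fog node's service time exceeds
the round-trip difference (this crossover is itself tested). Latency is
measured sensor emission → actuator delivery. In the queueing-free regime
(inter-arrival > per-message occupancy) the simulator reproduces the
closed-form path sum to 1e-9 ms.

## Problem sizes

The reference configuration used throughout tests and the acceptance
script: 200 records of 2 s at 256 Hz (S = 512), 30 training epochs, five
split seeds for the benchmark, 1000 simulated messages. Unit tests use
smaller datasets (tens of records, 0.5-0.6 s) where the property under
test does not depend on the full geometry.

## Known limitations

* The decoder as printed cannot reconstruct beta-band detail through the
  140-point internal grid (Nyquist ≈ 17.5 Hz at the default S); the
  reconstruction loss therefore plateaus well above zero on oscillatory
  data. The encoder's usefulness for classification does not depend on
  reaching low reconstruction error, and the descent property is what the
  autoencoder contract requires.
* MDI importance is known to inflate high-cardinality features; all 336
  latent pixels are continuous and exchangeable here, so the bias is
  uniform and the map remains comparable across pixels.
* The latency simulator models one sensor, one processing node and one
  actuator; no contention between multiple operators, no packet loss, no
  energy model.
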