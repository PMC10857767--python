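# Methods

## Wavelet dictionary

Atoms are parameterized by an integer oscillation period `P` (samples), a
support `t_s` (samples) and a shift `Δt` (samples) inside a power-of-two
analysis window of `N` samples.  Frequencies are stored exactly as periods
and converted to Hz on demand (`f_o = fs/P`), so enumeration is pure integer
arithmetic and bit-stable across runs.  The Haar enumeration admits periods
`P ∈ {N, N/2, …, 2}`, supports `t_s ∈ {P, 2P, …, N}` (power-of-two multiples)
and shifts that are multiples of `t_s`; the count is `Σ_P (2N/P − 1)`, i.e.
502 for `N = 256` and 247 for `N = 128`.  Ordering is canonical (descending
period, ascending support, ascending shift, constant atom last) and the
line-oriented JSON serialization round-trips bit-exactly.

Haar polarity starts at +1 (a `polarity` flag exists, default off): the
classifier is sign-invariant under a consistent convention.  The constant
atom is a distinct family, not a degenerate Haar, so scheduling and energy
accounting can treat it as direct integration.  Gabor atoms live on the same
lattice expanded by a configurable phase grid (default {0, π/2}) with
`σ = t_s/6`; no published atom count exists for a specific Gabor enumeration,
so none is asserted.

## Feature extraction and quantization

A feature is the Riemann sum `Σ x[n]·ψ[n] / fs` (signal-units·seconds).  The
1/fs scale is immaterial to classification but fixed so values have physical
units.  Quantization maps each feature to the nearest of `2^bits` uniform
levels spanning the per-feature range learned on the training split
(endpoints included, so the training min and max are exact levels and
quantization is idempotent); test values are clipped into range, mimicking a
fixed-range ADC.  The worst-case error is half the level spacing,
`range/(2·(2^bits−1))`.  Per-feature (rather than global) ranges were chosen
because feature magnitudes vary over orders of magnitude with support
length.  Features are z-scored with training-split statistics after optional
quantization, purely for optimizer stability.

## Classifier

A numpy implementation of a small fully-connected net: ReLU hidden layers,
softmax output, cross-entropy loss, full-batch Adam (lr 0.01).  Training is
a pure function of (seed, data): weights are initialized from a
`default_rng(seed)` stream with either Glorot-uniform kernels/zero biases or
uniform ±0.05 kernels and biases ("random_uniform").  The wrapper search
derives one seed per (step, candidate) — random initialization demonstrably
changes which subsets win, so reproducibility requires this discipline.
Degenerate training sets (any class absent) are rejected.  The default inner
budget is reduced (≈100 epochs) with the full budget available for final
refits; at these problem sizes the loss plateau is reached well before 100
epochs.

Metrics all derive from the confusion matrix: accuracy, per-class
recall/precision, and for binary tasks sensitivity, specificity and the
Matthews correlation coefficient (defined as 0, with a flag, when a
denominator factor vanishes).  `count_parameters` counts dense weights plus
biases and matches the trained model's tally exactly.

## Selection

Information gain uses 12 equal-width bins over the observed range (constant
features score 0; empty bins contribute nothing), entropies in bits.  The
top 100 candidates (configurable) enter the SFS.  Ties in both IG ranking
and SFS scoring break toward the lower dictionary/filter rank — a
deterministic rule that favors stronger filter evidence.

Scheduling is greedy interval partitioning by start time, which is optimal
for interval graphs; the adapted search evaluates admissibility on this
minimum count, not on any fixed prior assignment.  Extractors are
channel-agnostic (an input multiplexer selects the signal); a per-signal
mode is not implemented.

The optimized search scores `accuracy − λ·E(S∪{F})/E_ref` with `E_ref`
defaulting to the energy of a full-window Haar feature, making λ a
dimensionless trade-off weight; λ = 0 reduces bit-exactly to the adapted
search because both run the same engine.  No published closed form exists
for the energy-aware criterion; this linear penalty is the package's own
choice and is configurable.

Candidate subsets are scored on a held-out stratified validation split
(default 25% of the training windows).  A `split_policy="test"` mode scores
them on the test split instead — matching the original protocol of
evaluating `ACC` per candidate on the test set — but it leaks the test set
into selection and is therefore not the default.  Final metrics always come
from a refit on the full training split evaluated on the untouched test
split.

## Energy model

Per-feature energy: `(P_amp + P_int + P_wavelet)·t_s/fs + P_adc/F_s_adc`,
with `P_wavelet = 0` for constant atoms.  The symbol collision between
"shift" and "support duration" in the source formula is resolved to support
duration.  `P_wavelet` has no published value for the target technology and
is a required field: reports echo the value used.  The reference budget
carries the published component powers (5.04 µW amplifier, 625 nW
integrator, 0.3 µW / 40 kHz ADC, 0.7 µW anti-aliasing filter, 3.7 nJ/bit
radio, 2 kHz Nyquist rate, 0.9 µW A2I converter at compression 4, 120 mW /
270 ns in-sensor classifier).  Chains report acquisition, transmission and
classification energies separately; the A2F chain uses whole non-overlapping
windows (`floor(T/window_period)`), taking the conservative reading of an
ambiguous proration.  An optional shared-amplifier accounting is left to
future work; the per-feature formula as printed is the default and the upper
bound.

## Synthetic generators

The generators emulate the *statistical structure the method exploits*, not
physiology or biomechanics:

- **ECG-like**: one channel, 256 samples at 360 Hz, a stereotyped
  P-QRS-T pulse train with the R peak at sample 100 and an 85/15
  normal/abnormal prior; abnormal beats have a widened, lower QRS, no P
  wave and a shifted secondary peak.  Gaussian amplitude jitter (sd 0.05)
  and additive noise (sd 0.05 signal units against a unit R peak).
- **Inertial-like**: six channels, 128 samples at 50 Hz, six balanced
  classes.  Three static classes are distinct per-channel mean vectors
  (gravity projections) plus noise; three dynamic classes oscillate at
  1.5625 / 3.125 / 6.25 Hz — on the Haar frequency grid `fs/2^k` so a
  matching-period atom responds to exactly one class — with class-specific
  channel amplitude patterns, a 20% second harmonic and small phase jitter
  (sd 0.2 rad).

Classes are separable by a few dictionary atoms *by construction*: passing
end-to-end tests therefore demonstrates that the pipeline recovers structure
that is present, not that comparable accuracy would be reached on real
recordings (real ECG morphology variation, inter-subject HAR heterogeneity
and unsynchronized windows are all absent).  Default sizes (400 ECG / 360
inertial windows, stratified 70/30 split) keep every experiment desk-scale;
the end-to-end suite runs in well under a minute on one core.

An optional fixed-width-text reader ingests the pre-windowed smartphone HAR
dataset unchanged.  A reader for the arrhythmia database's waveform format
is not included; windowing per its beat annotations (R peak at sample 100,
34/14 record split) is documented in the data types for users who convert
those records to the container format themselves.

## Known limitations

- Analog non-idealities (mixer/integrator noise, offset, finite cut-off) are
  not modeled.
- The Gabor enumeration that would reproduce published Gabor dictionary
  sizes is unspecified; Gabor support is config-driven and size-agnostic.
- Headline real-data accuracies and chain-energy ratios depend on the real
  datasets, stochastic training and the unpublished wavelet-generator power;
  the package computes them for any configured budget/selection but asserts
  none.
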