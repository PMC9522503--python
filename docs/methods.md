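# Methods

This note documents the models implemented in `sleepstager`, the assumptions
behind them, the synthetic data they are validated on, and the numerical and
design choices made where the design was genuinely open.

## Pipeline overview

A recording is a sequence of 30 s single-channel EEG epochs at 100 Hz
(3000 samples each) with one AASM stage label per epoch, in the fixed order
(W, N1, N2, N3, REM) used by every vector and matrix in the package. The
pipeline is

    standardize ─→ TCN branch ──────────┐
                                         ├─→ per-branch weighted fusion ─→ merge ─→ HMM fine-tune
    spectrogram ─→ 1-max-pooling CNN ───┘

Each stage is independently usable; `TemporalContextSleepStager` wires them
together behind a scikit-learn estimator interface, and the `sleepstager` CLI
exposes them as subcommands with file handoffs.

## Preprocessing

* **Standardization** `S' = (S − μ)/δ`. The scope of μ, δ is configurable:
  `per_recording` (default) pools statistics over all epochs of one night,
  preserving the relative amplitude differences between stages (deep sleep is
  genuinely higher-amplitude than REM); `per_epoch` z-scores each epoch
  independently. A zero-variance (flat) epoch raises a dedicated error naming
  the recording and epoch rather than emitting NaNs.
* **Spectrogram.** Symmetric Hamming window of 2 s, 50% overlap, 256-point
  FFT, no padding: frame count `floor((L−W)/H)+1` — 29 frames for a
  3000-sample epoch — and 129 one-sided frequency bins. Log power is
  `log(power + ε)` with ε = 1e−10 so silent frames stay finite.
* **Filter bank.** 20 triangular filters with linearly spaced centers over
  0.5–49 Hz (the EEG-relevant band below the 50 Hz Nyquist), 50% overlap
  between neighbors, each row normalized to unit sum. Filters act on linear
  power, and the result is re-logged (standard filter-bank practice); the
  full 29×129 log spectrogram remains available for inspection
  (`apply_bank=False`). Linear spacing rather than Mel-style warping was
  chosen because sleep-relevant rhythms (delta through spindle frequencies)
  occupy the low end roughly uniformly; the spacing and range are
  configurable.

## Branch networks

Both branches are *one-to-many context* models: from epoch *n* alone they
emit three 5-class distributions — P(yₙ₋₁|xₙ), P(yₙ|xₙ), P(yₙ₊₁|xₙ).

**TCN (temporal branch).** Five residual temporal blocks over the raw
standardized signal; block *i* uses dilation `b^i` and contains two dilated
causal convolutions, each followed by ReLU and dropout, plus a residual
connection (pointwise convolution where channel counts differ). Causal
left-padding keeps sequence length constant, and causality is exact: an
activation at time *t* never depends on inputs after *t* (probe-tested).
The closed-form receptive field of a stack of single convolutions,
`w = 1 + (k−1)(bⁿ−1)/(b−1)`, governs the coverage requirement w ≥ 3000;
the default k = 7, n = 5, b = 5 gives w = 4687, and `min_layers` inverts the
formula by ceiling search (the smallest *n* whose receptive field reaches the
target — implemented as the explicit minimal-n search, which is the
well-defined form of the inversion). k ≥ b is enforced so the receptive
field has no holes. The length-3000 feature sequence is summarized by its
final time step (the causal summary of the whole epoch; a global-average
alternative sits behind `head_pool="mean"`).

**CNN (spectral branch).** One convolutional layer over the 29×20
filter-bank spectrogram with kernels (20, 3), (20, 5), (20, 7) — each kernel
spans the full frequency axis, so feature maps are 1-D in time — followed by
global 1-max pooling (keeping each map's single most prominent activation),
dropout, and the three softmax heads. The 400 total filters are split
133/133/134 across the three widths; the total-vs-per-width reading of the
filter count is configurable via `n_filters_total`.

**Loss and training.** The multitask loss sums the cross-entropies of the
three subtasks per sample, averages over the batch, and adds `(λ/2)‖θ‖²`
over the weight matrices (λ = 1e−3 by default; biases are not penalized).
Epochs at a recording boundary simply drop the missing neighbor subtask.
Training uses Adam (default batch 20, learning rate 1e−4) with inverted
dropout (default rate 0.2), and retains the parameters of the epoch with the
best validation classification accuracy. Weight initialization is
fan-in-scaled Gaussian with a recorded seed; the output heads start at zero,
so an untrained network emits exactly uniform distributions. Both networks
are implemented directly in NumPy with hand-written backward passes
(verified against finite differences) — float32 throughout, deterministic
for a fixed seed on a single CPU thread.

## Adjacent-epoch fusion

Deciding epoch *n* combines the previous epoch's forward prediction, the
epoch's own classification, and the next epoch's backward prediction:

    P(yₙ) = (1/3) Σ_{i=n−1}^{n+1} αᵢ P(yₙ|xᵢ),   αᵢ = (PreACC(xᵢ)/ACC(xₙ))²,

with α = 1 for the current epoch. The accuracies are measured on the
validation split of the fold (test-set accuracies are unavailable at decision
time). At recording boundaries, missing terms are dropped and the 1/3
becomes 1/(number of present terms), keeping scores comparable across
positions. Each branch is fused separately, then the two branches' fused
score vectors are merged by an arithmetic mean before the argmax (an
elementwise geometric mean sits behind `branch_merge="geometric"`); the
cross-branch merge is not prescribed by the fusion formula itself, and the
arithmetic mean was chosen as the least-committal convex combination.
Argmax ties break toward the stage most prevalent in the training labels,
deterministically. Setting all α to 1 recovers balanced (unweighted)
fusion; disabling fusion reduces the decision to the per-epoch
classification — the pipeline's ablation variants are exactly these
switches, plus enabling/disabling the TCN branch and the HMM stage.

## HMM fine-tuning

Fused labels are the observation sequence of an HMM whose hidden states are
the true stages. The transition matrix is estimated from bigram counts of
the training hypnograms (never pooled across recording boundaries; a stage
never seen as a bigram source receives a uniform outgoing row), the emission
matrix row-normalizes the training-set confusion matrix of the fused
classifier (P(observed | true)), and the initial distribution is the
empirical stage frequency. Both matrices receive additive smoothing 1e−6 so
every observation sequence has positive path probability. A recording is
partitioned into consecutive non-overlapping windows of L = 17 epochs
starting at epoch 0 (the final remainder window may be shorter) and each
window is replaced by its Viterbi decode, computed in log space with ties
broken toward the lowest stage index. `select_window_length` scans candidate
L values on validation data and returns the most accurate (ties to the
smallest). Windowing trades context length against the decaying time
dependence between distant stages: too short and isolated errors at window
edges survive; too long and the Markov assumption over-smooths genuine short
stage bouts.

## Synthetic data

The generator emulates exactly the two statistical properties the pipeline
exploits, and nothing more:

* **Hypnogram structure.** A first-order Markov chain with 0.897
  self-transition mass — the observed fraction of adjacent same-label epoch
  pairs in overnight single-channel recordings — with the off-diagonal mass
  distributed along typical sleep-architecture routes (W↔N1, N1→N2, N2↔N3,
  N2↔REM favored; the exact split is a documented free default). Nights
  start mostly awake (initial distribution 0.6/0.2/0.1/0.05/0.05).
* **Spectral separability.** Per-stage spectral templates — W: alpha
  10±1 Hz, amplitude 1.0, 30 µV RMS; N1: theta 5.5 Hz, 0.5, 20 µV; N2:
  theta plus 13 Hz spindle band, 25 µV; N3: delta 1.2 Hz, 2.0, 60 µV; REM:
  low-amplitude theta plus weak 20 Hz activity, 15 µV — synthesized in the
  frequency domain as Gaussian bumps over a 1/f amplitude floor with uniform
  random phases, inverse-rFFT'd and scaled to the template RMS.

One seed drives a dataset; recording *i* uses the derived stream
`SeedSequence(seed, spawn_key=(i,))`, so enlarging a dataset never perturbs
existing recordings. The default dataset is 20 recordings × 200 epochs.

What the generator does **not** emulate: waveform morphology (K-complexes,
vertex waves), artifacts, inter-subject variability, EOG/EMG leakage, or
age- and pathology-related spectra. Passing tests on this data demonstrate
that the pipeline's machinery is correct and that its inductive biases work
when stages are spectrally separable and temporally persistent; they say
nothing about clinical-grade accuracy on real polysomnography.

## Numerical choices and degenerate inputs

* Log floor ε = 1e−10 on spectral power; HMM smoothing 1e−6.
* Symmetric (analysis-convention) Hamming window.
* Flat epochs, empty splits, non-stochastic matrices, non-one-hot targets,
  mismatched sequence lengths, and ablation configurations with no branch
  enabled all raise explicit errors.
* Viterbi ties: lowest stage index. Fusion argmax ties: training-prevalence,
  then lowest index. Window-length ties: smallest candidate. Distinct state
  paths can tie exactly in likelihood (same multiset of factors); any
  maximizer is a valid decode and the tie rule picks one deterministically.
* Metrics of zero-support classes are reported as 0 with a warning.

## Problem sizes used by the tests

The test suite and the end-to-end check run desk-scale configurations chosen
to exercise every component on one CPU core: the default 20×200-epoch
synthetic dataset; a TCN with 8 filters (3 Adam epochs, learning rate 1e−3,
dropout 0.1) and a CNN with 48 filters (8 epochs) on a single
leave-one-subject-out fold; 100 000-epoch hypnograms for parameter-recovery
checks; and exhaustive Viterbi enumeration up to length 6 over 3 states.
The published-scale hyperparameters (50 TCN filters, 400 CNN filters, batch
20, learning rate 1e−4, 20-fold leave-one-subject-out with 4 validation
subjects) remain the library defaults.

## Known limitations

* The NumPy networks are CPU-bound and sized for method validation, not for
  benchmark-scale training on full clinical datasets.
* The EDF path reads one channel and assumes epoch-aligned labels; in-bed
  period trimming indices must be supplied by the caller, and multichannel
  fusion (EOG/EMG) is out of scope.
* Fusion weights are measured, not learned; the HMM uses hard labels as
  observations (no soft-score emissions, no forward–backward smoothing).
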