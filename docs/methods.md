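# Methods

## Problem and scope

`eegnda` studies how two kinds of noise augmentation affect multi-label
classification of hand-action events from multi-channel EEG:

- **Natural noise augmentation** — enlarging the input window to N samples
  so that signal from neighboring, action-irrelevant time regions enters
  every training example. The window's 6-bit label is read from the binary
  trigger matrix at a single sample index controlled by an *offset*:
  0 labels the first window sample, 0.5 the middle, 1 the last
  (`label_index = start + floor(offset * (N - 1))`). Offsets 0 and 1 mean
  the labeled instant sits at a window edge, so the window mostly contains
  signal *after* or *before* the labeled moment.
- **Synthetic noise augmentation** — adding i.i.d. Gaussian noise
  `N(0, sigma^2)` to every channel-time entry of the normalized signal,
  with sigma in {0.001, 0.01, 0.1, 0.2} in z-scored units.

The downstream characterization uses per-class / micro / macro ROC-AUC as
a function of N, steady-region summary statistics, LOWESS smoothing, and
detrended fluctuation analysis (DFA) with Hurst exponents fit over full,
short (< 1000 samples, i.e. < 2 s at 500 Hz) and long scale bands.

## Synthetic data generator

Real grasp-and-lift recordings are 32-channel, 500 Hz EEG with six binary
trigger series (HandStart, FirstDigitTouch, BothStartLoadPhase, LiftOff,
Replace, BothReleased), each active run lasting ~0.3 s (150 samples), with
FirstDigitTouch and BothStartLoadPhase strongly overlapping and some
classes showing anticipatory cortical activity before movement onset. The
generator reproduces those structural facts:

- **Background**: per-channel white Gaussian noise spectrally shaped to
  1/f^beta power (beta = 1, pink, by default — the dominant natural EEG
  background), z-scored to unit variance. DC is removed, as acquisition
  hardware does.
- **Class signatures**: per class a Hann-windowed sinusoid (frequency
  drawn once per seed from 6–28 Hz, the physiological theta–beta range)
  projected onto a fixed random channel-weight vector, spanning
  `[onset - lead, onset + action + lag)`. `snr` is the peak template
  amplitude relative to the unit-variance background; `snr = 0` disables
  injection while consuming the identical random stream, so the injected
  field is recoverable exactly as a difference of two runs (used as a test
  oracle). Damped-oscillation templates are an intuitive ERP-like shape;
  no more specific generative model is claimed.
- **Anticipatory activity**: default per-class lead times are 0.4 s for
  HandStart, Replace and BothReleased and 0.1 s for the others, mirroring
  the qualitative observation that those classes show pre-onset activity;
  fully configurable, and the scaled validation profile uses symmetric
  lead = lag so the offset comparison is not confounded by asymmetry.
- **Trial placement**: onsets are scheduled in interleaved class order on
  an even grid with uniform jitter and a minimum inter-trial gap (default
  1 s); the forced-overlap pair shares onsets exactly.

What the generator does **not** emulate: volume conduction and electrode
geometry, non-stationarity across a session, artifacts (blinks, EMG), and
realistic cross-channel correlation structure of background EEG. Passing
tests on synthetic data therefore demonstrate that the pipeline measures
what it claims under controlled conditions, not that the same effect sizes
would be observed on real recordings.

The same module provides exact fractional Gaussian noise (circulant
embedding / Davies–Harte) with prescribed Hurst exponent, used solely to
validate the DFA estimator; exactness means the autocovariance is the
closed-form fGn autocovariance, not an approximation.

## Windowing, labeling, normalization, splits

Windows are drawn with uniformly random start indices over the whole
timeline; labels are the six trigger values at the offset-controlled
index. Per-channel z-scoring precedes noise injection (noise is specified
on the normalized scale), and statistics can be computed on a subset and
reused on held-out data. `label_index` uses floor rather than round — a
deterministic choice avoiding round-half-even ambiguity. The
82% / 9% / 9% train/validation/test split uses a seeded permutation
(largest-remainder apportionment of counts); a `time-blocked` mode that
cuts the recording into three contiguous segments exists because random
splitting of overlapping windows permits train/test leakage — the default
remains `random`, matching the study protocol. Gaussian noise defaults to
all three splits (it models the acquisition environment, not a train-time
trick); a train-only switch exists for conventional-augmentation
comparisons. Windows are drawn uniformly, so negatives dominate at the
ratio set by event density; an optional positive-enrichment knob exists
but is off by default.

## Classifier

The "vanilla" network: three convolutional stages with 32/64/128 filters
and kernels 3/5/7 sliding along time over all input feature maps, each
followed by batch normalization, ReLU, max pooling (2) and dropout 0.1,
then dense layers (default widths 128, 64) ending in 6 independent
sigmoid outputs trained with mean binary cross-entropy — the classes
co-occur, so the task is multi-label and per-class scores are required
for per-class AUC. The network is implemented directly on numpy arrays
with hand-written backward passes (verified against central-difference
numerical gradients to 1e-5 relative error) and Adam. Choices the
architecture description leaves open, resolved here: He-normal
initialization; conv bias kept (redundant under batch normalization but
harmless); validation every `checkpoint_every` batches plus epoch end,
keeping the lowest-loss and highest-accuracy snapshots; "accuracy" is
per-label binary accuracy at threshold 0.5 (exact-match available);
optimizer Adam with learning rate 1e-3 and batch size 64 by default;
global-norm gradient clipping at 5.0, which stabilizes the few-step
single-epoch regime. Training is deterministic given the weight seed and
the training seed. Batch-norm inference uses running statistics with
momentum 0.9 — a deliberately short memory, since a single epoch provides
few update steps.

## Sweep and summaries

For every (N, offset, sigma) grid cell one model is trained for a single
epoch and evaluated on the test split for both checkpoints. The default
grid is N = 100..2000 step 100 (20 iterations), offsets {0, 0.5, 1},
sigma {0, 0.001, 0.01, 0.1, 0.2}. Per-cell seeds are SHA-256 hashes of
(master seed, N, offset, sigma index) truncated to 31 bits, so cells are
independent and individually reproducible. A failed cell is logged with
its coordinates and skipped; the sweep continues. Steady-region statistics
(mean, sample std, max, min, range; default region N in [1000, 10000])
and LOWESS smoothing (tricube weights, degree-1 local fits over
ceil(frac·n) nearest neighbors, frac 0.3, no robustness iterations)
summarize the AUC-vs-N curves. Classes with single-class labels in a test
split have undefined AUC; they are excluded from the macro mean and
flagged rather than imputed at 0.5, which would bias macro AUC toward
chance at small N.

## DFA

Profile = cumulative sum of the mean-centered series; at each scale n the
profile is partitioned into floor(len/n) non-overlapping windows twice
(forward and reverse, so trailing samples are used), a degree-1 polynomial
is removed per window (DFA-1, the canonical default), and F(n) is the RMS
residual over all windows of both passes. Scales are log-spaced, about 20
per decade, from 8 to length/4 (capped at 10000) — log spacing weights
decades equally in the log-log fit. H is the OLS slope of log F vs log n,
fit over the full range and over scales strictly below/above the band
split (default 1000 samples = 2 s at 500 Hz); zero-F scales are excluded
with a warning, and a band with fewer than two usable scales is reported
NaN rather than failing the whole analysis. Table outputs round H to two
decimals (full precision retained internally). The per-action series for
EEG-mode DFA concatenates `[onset - pre, onset + post)` segments of the
cross-channel mean in temporal order; both this EEG mode and a direct
series mode (e.g. for AUC-vs-N series) are exposed, since either signal
can meaningfully be DFA-analyzed and the choice is left to the caller.

## Scaled validation profile

The full study grid (20 N values, 5 sigmas, tens of thousands of windows)
is a multi-hour GPU-era computation; the package's validation suite runs a
scaled-down profile chosen once for desk-scale hardware (`demo_config`):
N = 100..600 step 100 with steady region [300, 600]; sigma in {0, 0.2};
900 windows per cell split 82/9/9; a 3-minute, 32-channel synthetic
recording with 50 trials per class (minimum gap 0.5 s), symmetric
lead = lag = 0.2 s signatures, and snr 2.5 — chosen so the steady-region
macro AUC lands in the 0.85–0.95 band, clearly above chance and below
ceiling; batch size 8 and learning rate 5e-3, because a single epoch over
~740 training windows allows only ~92 optimizer steps and the default
(64, 1e-3) barely moves the weights in that budget. Under this profile the
steady-region macro AUC at offset 0.5 exceeds offsets 0 and 1 in at least
4 of 5 fixed master seeds, and the sigma = 0.2 shift of mean macro AUC is
smaller than the across-seed spread at sigma = 0 — the two qualitative
findings the full-scale study reports.

## Numerical and degenerate-input policy

- Zero-variance channels normalize to all-zeros (no division by zero).
- Sample (ddof = 1) standard deviation everywhere a "± std" is reported.
- AUC uses the rank formulation with ties counted 1/2.
- LOWESS falls back to the weighted mean when the local design is
  singular (duplicate x).
- Sigmoid/BCE are computed with clipping at 1e-7 to avoid log(0);
  training aborts with a descriptive error on non-finite loss.
- fGn circulant eigenvalues are clipped at zero only to absorb float
  round-off (they are nonnegative in exact arithmetic for all H in (0,1]).

## Known limitations

- Single-epoch training at desk scale is high-variance; per-cell AUC
  fluctuates strongly (this fluctuation is itself an object of study in
  the DFA stage). Qualitative orderings are asserted over multiple master
  seeds, never from a single run.
- The "PAS-to-noise ratio" notion is represented operationally by the
  generator's snr plus window composition; no closed-form equation for it
  is defined, so no quantitative claim about it is made.
- The reader treats any GAL-dialect file pair as one continuous timeline;
  subject/series segmentation and subject-wise cross-validation are out
  of scope.
- DFA significance testing and multifractal extensions are out of scope.
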