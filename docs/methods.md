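# Methods

This note records the models implemented by `megdecode`, the assumptions
behind them, the parameters that matter, and the design decisions taken
where more than one reading was defensible.

## Trial model and preprocessing

A trial is a tensor `X ∈ R^{T×C}` at a stated sampling rate with an event
(cue) onset at a known sample index.  The container (`TrialSet`) stores the
event index explicitly per trial rather than fixing a convention, because
both "event at 1.5 s of a 3.5 s epoch" and "event at 0.5 s" geometries occur
in practice; every downstream operation (cropping, obscuring) reads the
stored index.  All sample indices are 0-based.

Preprocessing is deliberately minimal and ordered: polyphase resampling
(upsampling refused unless requested), zero-phase Butterworth band-pass
(forward–backward, order 4 per direction — no group delay, so event indices
stay valid; stop-band attenuation far exceeds 20 dB one octave out), then
epoching.  Cue onsets too close to a recording edge are skipped with a
logged warning rather than failing the whole run.

**Cropped-trial augmentation.** Each trial is multiplied into fixed-length
contiguous crops, each required (by default) to contain the event.  The
candidate count at stride 1 is `(duration − window) × rate` — one less than
the fencepost count — so a 2 s window over 3.5 s at 200 Hz gives exactly
300 crops, the augmentation ratio of the reference pipeline.  Event
containment uses the half-open convention `s ≤ event < s + window`.

## SCNN

The spatial stage applies stacked 1-D convolutions *across the channel
axis* at each time point, sharing weights across time.  A layer with
kernels of `n` taps maps `P` channel positions to `P − n + 1` (valid
convolution, no padding anywhere in the network); the configuration is
rejected unless the stack lands on exactly one position, which is what
makes the stage a learned, non-linear generalization of a spatial filter.
Later spatial layers span positions × all incoming kernel maps (the
standard convolutional reading; the per-layer bookkeeping
`T×C×1 → T×(C−C')×K₁ → T×1×K₂` holds under it).  Temporal convolution then
filters each component sequence (`F` filters, again valid), followed by
optional non-overlapping pooling and a dense classifier head.

Choices worth recording:

- **No conv/dense-hidden biases**: batch normalization follows every
  activation and absorbs them; the final output layer keeps a bias.
- **Activations**: ReLU, ELU, SELU (λ ≈ 1.0507, α ≈ 1.6733); an `identity`
  option exists so tests can reduce the spatial stage to an exact linear
  map and compare against explicit matrix multiplication.
- **Pooling**: average by default (it acts as a low-pass/parameter
  reduction step); max-pooling is available behind a flag since both appear
  in practice.
- **Dropout**: spatial dropout (whole kernel maps) on convolutional stages,
  ordinary dropout on dense stages.
- **Initialization**: variance scaling by fan-in (He gain for ReLU, LeCun
  otherwise), seeded from the config.
- `plan_shapes` validates a configuration and predicts every stage's shape
  and the trainable-parameter count; the test suite asserts it equals the
  built network over random configurations, so shape arithmetic cannot
  silently drift from the implementation.

## Ra-SCNN

The recurrent extension keeps the SCNN conv stages as a front-end producing
a feature sequence `f ∈ R^{T'×J}`, and feeds an LSTM whose step-t input is
an attention summary of the *entire* sequence.  The scoring network `a` is
a feed-forward stack (depth configurable, width = LSTM hidden units,
`tanh` units) shared across positions; its input at position t' is
`[f_{t'}; h_{t−1}]` and its output is one score per feature, giving scores
`e ∈ R^{J×T'}` per step.  Softmax over positions (stable, max-subtracted)
yields weights with exact row sums of 1, and the step input is
`x_t[j] = Σ_i α_{j,i} f_{i,j}`.  This "score each position against the
recurrent state" reading keeps the parameter count independent of sequence
length and reduces to a no-op (α = 1) for a length-1 sequence.  The head
uses either the full output sequence or the last state.  Recurrent weights
are excluded from L2 regularization; the front-end always receives
gradient (asserted in tests).

## Training protocol

Evaluation is subject-wise everywhere.  `assign_folds` sorts subjects by
trial count (descending) and greedily assigns each to the lightest fold
(ties → lowest index), approximately equalizing fold totals; held-out test
subjects appear in no fold, and the suite asserts the three subject sets
never intersect.  Losses: cross-entropy against one-hot or
neighbour-smoothed targets (interior 0.6/0.2/0.2, boundary 0.8/0.2 —
encoding that adjacent ordinal classes are partially correct); optional
per-class weights `1 − n_class/n_total`; optional L2 on non-recurrent
weights.  Optimizers: SGD (momentum 0.9) or Adam, with an optional
multiplicative step decay.  Input scaling is configurable: training-fold
statistics, or per-trial per-channel z-scoring (removes multiplicative
subject/sensor gain differences — the right choice when the signal of
interest is relative spectral content).  A non-finite loss aborts the fold
with a diagnostic instead of producing silent garbage.

Transfer evaluation freezes all weights, extracts penultimate-stage
features and trains a linear max-margin (SVM) head; a single-class training
set degenerates to constant prediction by construction.  Hyperparameter
search is a pluggable driver; the built-in default is seeded random search
(uniform / log-uniform / integer / choice dimensions), with tree-structured
Parzen estimation usable through the driver hook where such a library is
available.

## Interpretation suite

**Activation maximization.** `x ← x + η·g/RMS(g)` with
`g = ∇(f_o(x) − θ·Σx²)`, initialized from 1/f noise (or zeros), default
η = 0.2, θ = 0.05, up to 10 000 iterations, stopping after 5 steps without
improvement (> 1e−8, a tolerance chosen here).  Because the RMS-normalized
step has constant magnitude, the raw iterate orbits the optimum at radius
~η; the implementation therefore tracks and returns the **best-objective
iterate**, and precision beyond η requires passing a smaller step size (the
closed-form tests use η = 0.005 to verify convergence to `a/(1+θ)` within
1%).  Two objective builders mirror the two useful input/output pairs:
model input → spatial-stage component, and spatial-stage output → class
logit.

**Topographies** use scattered bilinear (piecewise-linear) interpolation of
per-channel weights over a 2-D layout; the map equals the channel weight at
the channel's own coordinate, and values outside the convex hull are NaN.
**Spectrograms** are Hann-windowed PSDs with 64 FFT bins and 50-sample
overlap; the window length (unconstrained a priori) is set equal to the FFT
size and configurable.

**Obscuring profiles.** Obscured samples become `(x + 1000·n)/1001` — the
1:1000 weighting read as a convex mixture, since the unnormalized sum would
explode amplitudes — with `n` uniform noise scaled to each trial's
per-channel standard deviation.  `obscure_event` grows outward from the
event at a post:pre rate of `(T − event)/event` samples (6:1 for an event
0.5 s into 3.5 s); `obscure_ends` grows inward from both ends at the
mirrored rate.  The profile records the mean and standard deviation of the
correct-class **softmax probability** (comparable across trials, unlike
logits) over noise draws for each subject's highest-confidence correctly
classified trial per task, and a least-squares slope with Pearson r and p
can be fitted to any segment.

**Baseline controls.** Condition (a) classifies event-free baseline
recordings directly; condition (b) classifies accurate trials minus the
subject's across-task mean baseline.  A decoder keyed to event-locked
structure should be near chance on (a) and stay accurate on (b); baselines
shorter than the model input raise an explicit error rather than being
silently cropped.

## Comparison features

Rectangular windows of 50 ms with 25 ms overlap
(count = `⌊(epoch − window)/hop⌋ + 1`, hence 79 per 2 s epoch); per window:
means (plain/absolute/quadratic, each also over non-zero samples only),
variance, skewness/kurtosis (defined as 0 with a warning for constant
windows), RMS, log energy, FFT magnitudes (8-point by default for 200 Hz
signals — the window truncated to 8 samples; zero-padding selectable),
LPC coefficients (autocorrelation/Levinson–Durbin method, order 4 by
default), and the circular autocorrelation `iFFT(|FFT(w)|²)`, verified
against direct `Σ_n w_n w_{(n+k) mod N}` to 1e−10.  Component mixing is an
injected matrix (identity by default) — a statistically independent
decomposition can be plugged in, but no ICA solver is bundled.  Selection
keeps columns with Bonferroni-corrected Pearson `p < α/n_features` **and**
`|r| > r_min` against a continuous target; constant columns are excluded
with a warning.

## Synthetic data: what it does and does not emulate

The generator draws per-trial, per-channel backgrounds in the frequency
domain: amplitudes ∝ `f^(−γ/2)` (default γ = 1, a conventional choice for
encephalographic spectra), uniform random phases, inverse transform, scaled
so the per-channel variance is *exactly* `noise_sd²` (the amplitudes are
deterministic, so Parseval gives the variance analytically; the Nyquist bin
is treated as an ordinary bin — its power is negligible under 1/f).  A
class effect with multiplier `m` adds a sinusoid (frequency uniform in the
band per trial, random phase) whose power is `(m−1)×` the background band
power, so band power scales exactly by `m` and `m = 1` is exactly "no
effect"; with the post-event flag the oscillation starts at the event with
a 50 ms cosine ramp.  Subjects carry ±10% per-channel gain jitter (shared
between their trials and baselines) so subject-wise evaluation is harder
than trial-wise.  Baselines are the same background process without
effects, event index marked absent.

Not emulated: sensor physics and forward head-modelling, artifacts (ocular,
cardiac, movement), non-stationary background dynamics, inter-subject
spectral variability beyond gain.  Passing tests therefore demonstrate
that the pipeline recovers planted spectral structure under realistic
1/f statistics — not that it handles artifact-laden recordings.

## Reference experiment and problem sizes

The parameter-recovery study (`recipes.py`) uses 24 subjects × 40 trials,
32 channels, 2 s at 200 Hz, class effects 8–12 Hz vs 18–22 Hz at ×2 band
power on 8 channels, 4 held-out test subjects, 5 folds.  The decoder is
deliberately small: one collapsing spatial layer (4 kernels), 12 temporal
filters of 33 taps (~165 ms, ~1.2 Hz-wide mainlobe at 200 Hz — enough to
separate bands 6 Hz apart), **global** average pooling, linear readout;
ReLU; spatial dropout 0.2; L2 1e−4; Adam 3e−3 with ×0.5 decay every 20 of
60 epochs, batch 64, per-trial standardization.  Global pooling matters:
with a wide pooled feature map the network can memorize training subjects
(perfect training accuracy, chance on held-out subjects), whereas a
readout that sees only per-filter mean rectified amplitudes is forced into
the band-power representation that generalizes (mean held-out accuracy
0.94 at this size, ~5 minutes on one CPU).  Example scripts run reduced
sizes (e.g. 16 × 40, 3 folds) chosen to finish in a couple of minutes while
still showing above-0.85 held-out accuracy.

## Numerical choices and degenerate inputs

- All arithmetic float64; softmax/log-softmax max-subtracted.
- Batch normalization: per-feature over all other axes; training mode uses
  batch statistics and updates running averages (momentum 0.9, ε = 1e−5);
  evaluation mode is deterministic.
- Dropout masks are drawn from a model-owned seeded generator; evaluation
  mode applies none.
- Empty trial sets round-trip through the container; tampered manifests
  raise integrity errors; unknown config keys are rejected by the CLI with
  the list of valid keys.
- The autodiff engine frees each computation graph eagerly after
  `backward()` (iterative topological sort, explicit tape teardown) so
  long training runs hold constant memory.

## Known limitations

- The attention score/weight indexing admits more than one reading; the
  implemented one (scores per feature, softmax over positions, scoring
  network shared across positions) is self-consistent and tested, but
  alternatives exist.
- No vendor-format readers (CTF/FIF/EDF): any `(trials, labels, metadata)`
  arrays can be wrapped into a `TrialSet`, and the container format is a
  documented `.npy` + JSON manifest.
- The feature inventory implements the named feature *kinds*, not any
  particular extraction toolkit's full catalogue; printed feature totals of
  such toolkits are not reproduction targets.
- Training the Ra-SCNN is markedly slower than the SCNN (a Python-level
  recurrence over the feature sequence); it is exercised at small scale in
  the tests.
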