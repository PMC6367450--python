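"""Model interrogation: activation maximization, topographies, spectrograms,
obscuring profiles and baseline controls.

Activation maximization synthesizes an input that maximizes a chosen model
output by regularized gradient ascent,

    x_gen = argmax_x ( f_o(x) - theta * sum_i x_i^2 ),

starting from random data with a 1/f spectral prior (matching
encephalographic backgrounds) and normalizing each gradient step by its RMS
for stable progress.  Two input/output pairs are typical: model input ->
final spatial-stage output, and spatial-stage output -> class logits.

Obscuring profiles measure the model's correct-class output as progressively
more of a trial is replaced by noise (a 1:1000 signal:noise mixture), grown
either outward from the event or inward from the trial ends, at a post:pre
rate matching the trial geometry (6 samples after the event per 1 before,
for an event 0.5 s into a 3.5 s trial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal, stats

from .autodiff import Tensor
from .data import NO_EVENT, TrialSet
from .synthgen import one_over_f_noise

logger = logging.getLogger(__name__)

__all__ = [
    "MaximizationConfig",
    "MaximizationResult",
    "ObscuringProfile",
    "maximize_activation",
    "class_logit_objective",
    "spatial_unit_objective",
    "temporal_class_objective",
    "topography_map",
    "activation_spectrogram",
    "obscure_trial",
    "obscuring_profile",
    "fit_profile_slope",
    "baseline_control",
]


# ---------------------------------------------------------------------------
# Activation maximization


@dataclass(frozen=True)
class MaximizationConfig:
    """Gradient-ascent settings.

    step_size: ascent rate applied to the RMS-normalized gradient.
    l2_theta: weight of the L2 penalty on the generated input.
    Stops after ``patience`` consecutive steps without objective improvement
    (> min_improvement) or at ``max_iters``.
    """

    step_size: float = 0.2
    l2_theta: float = 0.05
    max_iters: int = 10_000
    patience: int = 5
    min_improvement: float = 1e-8
    init: str = "one_over_f"  # or "zeros", "given"
    sampling_rate: float = 200.0
    spectral_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.l2_theta < 0:
            raise ValueError("l2_theta must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.init not in ("one_over_f", "zeros", "given"):
            raise ValueError("init must be one_over_f / zeros / given")


@dataclass
class MaximizationResult:
    x_gen: np.ndarray  # best-objective iterate
    objective_trace: list
    stop_reason: str  # "converged" or "max_iters"


def _init_point(shape, cfg: MaximizationConfig) -> np.ndarray:
    if cfg.init == "zeros":
        return np.zeros(shape)
    rng = np.random.default_rng(cfg.seed)
    if len(shape) >= 2:
        # time on the second-to-last axis (…, T, C)
        lead = shape[:-2] + (shape[-1],)
        x = one_over_f_noise(
            rng, lead, shape[-2], cfg.sampling_rate, cfg.spectral_exponent, 1.0
        )
        return np.moveaxis(x, -1, -2)
    return one_over_f_noise(rng, (), shape[0] if shape else 1, cfg.sampling_rate,
                            cfg.spectral_exponent, 1.0).reshape(shape)


def maximize_activation(objective, shape, cfg: MaximizationConfig, x0=None) -> MaximizationResult:
    """Regularized gradient ascent of ``objective`` over an input of ``shape``.

    ``objective(x)`` takes a numpy array and returns ``(value, grad)`` where
    ``grad`` is d value / d x.  The ascent maximizes value - theta * sum(x^2),
    stepping ``x += step_size * g / rms(g)``, and returns the best-objective
    iterate.  A non-finite objective aborts with the partial trace.
    """
    if cfg.init == "given":
        if x0 is None:
            raise ValueError("init='given' requires x0")
        x = np.array(x0, dtype=np.float64)
    else:
        x = _init_point(tuple(shape), cfg)
    trace = []
    best_x, best_obj = x.copy(), -np.inf
    stall = 0
    stop_reason = "max_iters"
    for _it in range(cfg.max_iters):
        value, grad = objective(x)
        obj = float(value) - cfg.l2_theta * float(np.sum(x**2))
        if not np.isfinite(obj):
            logger.error("non-finite objective at iteration %d; aborting", _it)
            return MaximizationResult(best_x, trace, "aborted")
        trace.append(obj)
        if obj > best_obj + cfg.min_improvement:
            best_obj, best_x = obj, x.copy()
            stall = 0
        else:
            stall += 1
            if stall > cfg.patience:
                stop_reason = "converged"
                break
        g = grad - 2.0 * cfg.l2_theta * x
        rms = np.sqrt(np.mean(g**2))
        if rms == 0.0:
            stop_reason = "converged"
            break
        x = x + cfg.step_size * g / rms
    return MaximizationResult(best_x, trace, stop_reason)


def _tensor_objective(fn):
    """Wrap a Tensor->scalar-Tensor function into a (value, grad) objective."""

    def objective(x_np):
        x = Tensor(x_np, requires_grad=True)
        out = fn(x)
        out.backward()
        return float(out.data), x.grad

    return objective


def class_logit_objective(model, class_index: int):
    """Objective: the logit of ``class_index`` for a single input (T, C)."""

    def fn(x):
        return model.forward(x.reshape(1, *x.shape))[0, class_index]

    return _tensor_objective(fn)


def spatial_unit_objective(model, component: int):
    """Objective: mean activation of one spatial-stage component over time."""

    def fn(x):
        s = model.spatial_output(x.reshape(1, *x.shape))
        return s[0, :, component].mean()

    return _tensor_objective(fn)


def temporal_class_objective(model, class_index: int):
    """Objective over the *spatial-stage output* sequence (T, S): class logit
    of the downstream temporal + dense stages."""

    def fn(s):
        feats = model.feature_sequence(None, False, from_spatial=s.reshape(1, *s.shape))
        return model.head(feats, False)[0, class_index]

    return _tensor_objective(fn)


# ---------------------------------------------------------------------------
# Topography maps and spectrograms


def topography_map(channel_weights, layout, grid_shape=(64, 64)):
    """Interpolate per-channel weights onto a planar grid (bilinear).

    layout : (C, 2) channel coordinates.  Returns (grid, (xs, ys)); grid
    values outside the channels' convex hull are NaN.  The interpolated value
    at a channel's own coordinate equals that channel's weight.
    """
    w = np.asarray(channel_weights, dtype=np.float64)
    pts = np.asarray(layout, dtype=np.float64)
    if pts.shape != (len(w), 2):
        raise ValueError("layout must be (C, 2)")
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    if xmax == xmin or ymax == ymin:
        raise ValueError("degenerate layout: all channels share a coordinate")
    xs = np.linspace(xmin, xmax, grid_shape[1])
    ys = np.linspace(ymin, ymax, grid_shape[0])
    gx, gy = np.meshgrid(xs, ys)
    grid = interpolate.griddata(pts, w, (gx, gy), method="linear")
    return grid, (xs, ys)


def activation_spectrogram(sequence, sampling_rate, nfft: int = 64, noverlap: int = 50):
    """Hann-windowed power spectral density spectrogram in dB.

    64 FFT bins with 50-sample window overlap by default; window length
    equals the FFT size.  Returns (freqs, times, power_db).
    """
    x = np.asarray(sequence, dtype=np.float64)
    if x.shape[-1] < nfft:
        raise ValueError(f"sequence length {x.shape[-1]} < window length {nfft}")
    f, t, sxx = signal.spectrogram(
        x, fs=sampling_rate, window="hann", nperseg=nfft, noverlap=noverlap, nfft=nfft,
        detrend=False, scaling="density", mode="psd",
    )
    return f, t, 10.0 * np.log10(sxx + 1e-20)


# ---------------------------------------------------------------------------
# Obscuring profiles


@dataclass
class ObscuringProfile:
    schedule: str  # "obscure_event" or "obscure_ends"
    steps: np.ndarray  # obscured-sample counts per growth step
    mean: np.ndarray  # mean correct-class output per step
    std: np.ndarray  # std across noise draws (and trials) per step
    post_pre_rate: float = 1.0  # samples added post-event per pre-event sample


def _split_counts(n_obscured: int, event_index: int, T: int):
    """Split a total obscured count into (pre, post) at the geometric ratio."""
    post_per_pre = (T - event_index) / event_index
    pre = int(np.floor(n_obscured / (1.0 + post_per_pre)))
    pre = min(pre, event_index)
    post = min(n_obscured - pre, T - event_index)
    return pre, post


def obscure_trial(
    trial: np.ndarray,
    event_index: int,
    n_obscured: int,
    schedule: str = "obscure_event",
    noise: np.ndarray = None,
    rng=None,
    weighting: float = 1000.0,
) -> np.ndarray:
    """Replace ``n_obscured`` samples of a (T, C) trial by a 1:``weighting``
    signal:noise mixture.

    obscure_event grows outward from the event at a post:pre rate equal to
    (T - event_index) / event_index (6:1 for an event 0.5 s into a 3.5 s
    trial); obscure_ends grows inward from both ends at the mirrored rate
    (end:start).  Unobscured samples are untouched.
    """
    trial = np.asarray(trial, dtype=np.float64)
    T = trial.shape[0]
    if not (0 < event_index < T):
        raise ValueError("event_index must lie strictly inside the trial")
    if not (0 <= n_obscured <= T):
        raise ValueError("n_obscured must be in [0, T]")
    if schedule not in ("obscure_event", "obscure_ends"):
        raise ValueError(f"unknown schedule {schedule!r}")
    if n_obscured == 0:
        return trial.copy()
    if noise is None:
        rng = np.random.default_rng() if rng is None else rng
        scale = trial.std(axis=0, keepdims=True)
        noise = rng.uniform(-1.0, 1.0, size=trial.shape) * np.sqrt(3.0) * scale
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != trial.shape:
        raise ValueError("noise must match the trial's shape")
    pre, post = _split_counts(n_obscured, event_index, T)
    mask = np.zeros(T, dtype=bool)
    if schedule == "obscure_event":
        mask[event_index - pre : event_index + post] = True
    else:
        mask[:pre] = True
        if post:
            mask[T - post :] = True
    out = trial.copy()
    out[mask] = (trial[mask] + weighting * noise[mask]) / (1.0 + weighting)
    return out


def obscuring_profile(
    model,
    ts: TrialSet,
    schedule: str = "obscure_event",
    n_noise: int = 10,
    seed: int = 0,
    step_stride: int = 1,
    standardizer=None,
) -> ObscuringProfile:
    """Correct-class output vs. amount of trial obscured.

    For each subject (per task), the highest-confidence correctly classified
    trial is selected; for each growth step and each of ``n_noise`` uniform
    noise draws the softmax probability of the correct class is recorded.
    Growth steps add 1 pre-event sample and the geometric post:pre rate of
    post-event samples each, until the pre-event side is exhausted.
    """
    rng = np.random.default_rng(seed)

    def prep(x):
        return x if standardizer is None else (x - standardizer[0]) / standardizer[1]

    proba = model.predict_proba(prep(ts.data))
    pred = proba.argmax(axis=-1)
    correct = pred == ts.labels.astype(int)
    chosen = []
    for s in np.unique(ts.subject_ids):
        for task in np.unique(ts.task_ids):
            idx = np.flatnonzero((ts.subject_ids == s) & (ts.task_ids == task) & correct)
            if idx.size == 0:
                logger.warning("subject %s task %s: no correctly classified trial; skipped", s, task)
                continue
            conf = proba[idx, ts.labels[idx].astype(int)]
            chosen.append(idx[np.argmax(conf)])
    if not chosen:
        raise ValueError("no correctly classified trials to profile")
    ev = int(ts.event_index[chosen[0]])
    T = ts.n_samples
    rate = (T - ev) / ev
    ks = np.arange(0, ev + 1, step_stride)
    steps = np.minimum(np.round(ks * (1.0 + rate)).astype(int), T)
    means, stds = [], []
    noises = {}
    for i in chosen:
        trial = ts.data[i]
        scale = trial.std(axis=0, keepdims=True)
        noises[i] = rng.uniform(-1.0, 1.0, size=(n_noise,) + trial.shape) * np.sqrt(3.0) * scale
    for n_obs in steps:
        vals = []
        batch = []
        meta = []
        for i in chosen:
            for d in range(n_noise):
                batch.append(
                    obscure_trial(ts.data[i], ev, int(n_obs), schedule, noise=noises[i][d])
                )
                meta.append(int(ts.labels[i]))
        p = model.predict_proba(prep(np.stack(batch)))
        vals = p[np.arange(len(meta)), meta]
        means.append(float(np.mean(vals)))
        stds.append(float(np.std(vals)))
    return ObscuringProfile(schedule, steps, np.asarray(means), np.asarray(stds), rate)


def fit_profile_slope(steps, means):
    """OLS slope of an obscuring-profile segment.

    Returns (slope, pearson_r, p_value) for the regression of mean output on
    growth step.
    """
    steps = np.asarray(steps, dtype=np.float64)
    means = np.asarray(means, dtype=np.float64)
    if steps.size < 3 or steps.size != means.size:
        raise ValueError("need >= 3 (step, mean) pairs")
    res = stats.linregress(steps, means)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


# ---------------------------------------------------------------------------
# Baseline controls


def baseline_control(model, baselines: TrialSet, trials: TrialSet, standardizer=None) -> dict:
    """Two control conditions probing event-locked behaviour.

    (a) "baseline_alone": classify each subject's event-free baseline
        recordings directly (a model keyed to event-locked structure should
        be near chance);
    (b) "trial_minus_baseline": classify (trial - subject's across-task mean
        baseline) for each subject's best correctly classified trials
        (event-locked structure survives the subtraction).

    Returns ``{condition: {"correct": int, "incorrect": int}}``.
    """
    T = trials.n_samples
    if baselines.n_samples < T:
        raise ValueError(
            f"baseline length {baselines.n_samples} < model input length {T}; "
            "provide baselines at least as long as trials (no silent cropping)"
        )

    def prep(x):
        return x if standardizer is None else (x - standardizer[0]) / standardizer[1]

    counts = {
        "baseline_alone": {"correct": 0, "incorrect": 0},
        "trial_minus_baseline": {"correct": 0, "incorrect": 0},
    }
    trial_subjects = set(np.unique(trials.subject_ids).tolist())
    # condition (a): leading T samples of every baseline recording
    for i in range(baselines.n_trials):
        s = baselines.subject_ids[i]
        if s not in trial_subjects:
            logger.warning("baseline subject %s has no trials; skipped", s)
            continue
        seg = baselines.data[i, :T]
        pred = int(model.predict_proba(prep(seg[None]))[0].argmax())
        key = "correct" if pred == int(baselines.labels[i]) else "incorrect"
        counts["baseline_alone"][key] += 1
    # condition (b): accurate trials minus each subject's mean baseline
    proba = model.predict_proba(prep(trials.data))
    pred = proba.argmax(axis=-1)
    correct = pred == trials.labels.astype(int)
    for s in np.unique(trials.subject_ids):
        bmask = baselines.subject_ids == s
        if not bmask.any():
            logger.warning("subject %s has no baseline; skipped", s)
            continue
        mean_baseline = baselines.data[bmask, :T].mean(axis=0)
        for task in np.unique(trials.task_ids):
            idx = np.flatnonzero((trials.subject_ids == s) & (trials.task_ids == task) & correct)
            if idx.size == 0:
                continue
            conf = proba[idx, trials.labels[idx].astype(int)]
            i = idx[np.argmax(conf)]
            x = trials.data[i] - mean_baseline
            p = int(model.predict_proba(prep(x[None]))[0].argmax())
            key = "correct" if p == int(trials.labels[i]) else "incorrect"
            counts["trial_minus_baseline"][key] += 1
    return counts
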