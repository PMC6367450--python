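"""Trial container, container I/O, minimal preprocessing and crop augmentation.

The central object is :class:`TrialSet`: a tensor of ``n_trials x T x C``
samples plus per-trial labels, subject IDs, task IDs and the sample index of
the event (cue) onset.  Preprocessing covers the minimal pipeline used for
end-to-end decoding — resample, zero-phase band-pass, epoching — and the
cropped-trial augmentation that multiplies each trial into many fixed-length
sub-windows, each still containing the event onset.

The canonical preprocessing order is resample -> band-pass -> epoch ->
(optional) crop.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
#: event_index value marking "no event" (baseline recordings)
NO_EVENT = -1


class FormatError(ValueError):
    """Raised for unreadable or schema-invalid containers."""


class IntegrityError(ValueError):
    """Raised when a manifest disagrees with the stored array."""


@dataclass
class TrialSet:
    """Multichannel trials with aligned per-trial metadata.

    data : float array, shape (n_trials, T, C)
    labels : int array, shape (n_trials,)
    subject_ids : array, shape (n_trials,)
    task_ids : array, shape (n_trials,)
    event_index : int array, shape (n_trials,); ``NO_EVENT`` where absent
    sampling_rate : Hz
    """

    data: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    task_ids: np.ndarray
    event_index: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, T, C)")
        n = self.data.shape[0]
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        self.task_ids = np.asarray(self.task_ids)
        self.event_index = np.asarray(self.event_index, dtype=np.int64)
        for name in ("labels", "subject_ids", "task_ids", "event_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length n_trials={n}")
        bad = (self.event_index != NO_EVENT) & (
            (self.event_index < 0) | (self.event_index >= max(self.n_samples, 1))
        )
        if self.n_trials and bad.any():
            raise ValueError("event_index out of range [0, T)")

    # -- convenience -----------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def select(self, mask) -> "TrialSet":
        """Row subset (boolean mask or index array)."""
        return TrialSet(
            self.data[mask],
            self.labels[mask],
            self.subject_ids[mask],
            self.task_ids[mask],
            self.event_index[mask],
            self.sampling_rate,
        )

    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)


@dataclass(frozen=True)
class CropPlan:
    """Sliding-window augmentation plan.

    window_length is in seconds; stride in samples; require_event keeps only
    crops that contain the event onset.
    """

    window_length: float
    stride: int = 1
    require_event: bool = True

    def __post_init__(self):
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


# ---------------------------------------------------------------------------
# Container I/O: one array file + a JSON manifest.


def save_trialset(ts: TrialSet, path: str) -> dict:
    """Write ``ts`` under directory ``path`` as data.npy + manifest.json.

    Returns the manifest dict.
    """
    os.makedirs(path, exist_ok=True)
    np.save(os.path.join(path, "data.npy"), ts.data)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n_trials": int(ts.n_trials),
        "n_samples": int(ts.n_samples),
        "n_channels": int(ts.n_channels),
        "sampling_rate": float(ts.sampling_rate),
        "labels": ts.labels.tolist(),
        "subject_ids": ts.subject_ids.tolist(),
        "task_ids": ts.task_ids.tolist(),
        "event_index": ts.event_index.tolist(),
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh)
    return manifest


def load_trialset(path: str) -> TrialSet:
    mpath = os.path.join(path, "manifest.json")
    if not os.path.exists(mpath):
        raise FormatError(f"missing manifest.json under {path}")
    try:
        with open(mpath) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as e:
        raise FormatError(f"corrupt manifest: {e}") from e
    for key in ("schema_version", "n_trials", "sampling_rate", "labels"):
        if key not in manifest:
            raise FormatError(f"manifest missing key {key!r}")
    data = np.load(os.path.join(path, "data.npy"))
    expect = (manifest["n_trials"], manifest["n_samples"], manifest["n_channels"])
    if data.shape != tuple(expect):
        raise IntegrityError(f"array shape {data.shape} != manifest {tuple(expect)}")
    return TrialSet(
        data,
        np.asarray(manifest["labels"]),
        np.asarray(manifest["subject_ids"]),
        np.asarray(manifest["task_ids"]),
        np.asarray(manifest["event_index"], dtype=np.int64),
        manifest["sampling_rate"],
    )


# ---------------------------------------------------------------------------
# Preprocessing


def resample(ts: TrialSet, target_rate: float, allow_upsample: bool = False) -> TrialSet:
    """Polyphase resampling to ``target_rate`` Hz; rescales event indices."""
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if target_rate > ts.sampling_rate and not allow_upsample:
        raise ValueError(
            "refusing to upsample "
            f"({ts.sampling_rate} -> {target_rate} Hz); pass allow_upsample=True"
        )
    if target_rate == ts.sampling_rate:
        return replace(ts)
    frac = Fraction(target_rate / ts.sampling_rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(ts.data, up, down, axis=1)
    ratio = target_rate / ts.sampling_rate
    ev = np.where(
        ts.event_index == NO_EVENT, NO_EVENT, np.round(ts.event_index * ratio).astype(np.int64)
    )
    ev = np.where(ev == NO_EVENT, NO_EVENT, np.clip(ev, 0, data.shape[1] - 1))
    return TrialSet(data, ts.labels, ts.subject_ids, ts.task_ids, ev, target_rate)


def bandpass(ts: TrialSet, low: float, high: float, order: int = 4) -> TrialSet:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay)."""
    nyq = ts.sampling_rate / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high > nyq:
        raise ValueError(f"high={high} Hz exceeds Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=ts.sampling_rate, output="sos")
    data = signal.sosfiltfilt(sos, ts.data, axis=1)
    return TrialSet(
        data, ts.labels, ts.subject_ids, ts.task_ids, ts.event_index, ts.sampling_rate
    )


def epoch(
    recording: np.ndarray,
    sampling_rate: float,
    cue_times: np.ndarray,
    pre: float,
    post: float,
    labels=None,
    subject_id=0,
    task_id=0,
) -> TrialSet:
    """Cut a continuous (T_total x C) recording into cue-locked trials.

    Each trial spans ``pre`` seconds before to ``post`` seconds after its cue,
    giving T = round((pre+post) * rate) samples with the event at
    round(pre * rate).  Cues too close to a recording edge are skipped with a
    logged warning.
    """
    recording = np.asarray(recording, dtype=np.float64)
    if recording.ndim != 2:
        raise ValueError("recording must be (T_total, C)")
    if pre < 0 or post <= 0:
        raise ValueError("need pre >= 0 and post > 0")
    cue_times = np.atleast_1d(np.asarray(cue_times, dtype=np.float64))
    n_pre = int(round(pre * sampling_rate))
    n_len = int(round((pre + post) * sampling_rate))
    total = recording.shape[0]
    trials, kept = [], []
    for i, t in enumerate(cue_times):
        start = int(round(t * sampling_rate)) - n_pre
        if start < 0 or start + n_len > total:
            logger.warning("cue at %.3f s too close to recording edge; skipped", t)
            continue
        trials.append(recording[start : start + n_len])
        kept.append(i)
    n = len(trials)
    data = np.stack(trials) if n else np.empty((0, n_len, recording.shape[1]))
    if labels is None:
        lab = np.zeros(n, dtype=np.int64)
    else:
        lab = np.asarray(labels)[kept]
    return TrialSet(
        data,
        lab,
        np.full(n, subject_id),
        np.full(n, task_id),
        np.full(n, n_pre, dtype=np.int64),
        sampling_rate,
    )


# ---------------------------------------------------------------------------
# Cropped-trial augmentation


def crop_count(trial_duration: float, window_length: float, sampling_rate: float) -> int:
    """Number of candidate crop positions at stride 1.

    Uses the (duration - window) x rate convention, so a 2 s window over a
    3.5 s trial at 200 Hz yields 300 candidate positions; equal duration and
    window yield a single identity crop.
    """
    n = int(round((trial_duration - window_length) * sampling_rate))
    return max(n, 1)


def crop_augment(ts: TrialSet, plan: CropPlan) -> TrialSet:
    """Expand each trial into fixed-length crops per ``plan``.

    Crops are exact contiguous slices.  Start offsets run over
    {0, stride, 2*stride, ...} below the stride-1 candidate count; with
    ``require_event`` only offsets whose half-open window [s, s + W) contains
    the event are kept.  Labels and IDs are replicated; event_index is
    re-expressed relative to each crop.
    """
    duration = ts.n_samples / ts.sampling_rate
    if plan.window_length > duration + 1e-12:
        raise ValueError("window_length exceeds trial duration")
    win = int(round(plan.window_length * ts.sampling_rate))
    n_cand = crop_count(duration, plan.window_length, ts.sampling_rate)
    offsets_all = np.arange(0, n_cand, plan.stride)

    pieces, labs, subs, tasks, evs = [], [], [], [], []
    for i in range(ts.n_trials):
        ev = ts.event_index[i]
        offsets = offsets_all
        if plan.require_event:
            if ev == NO_EVENT:
                raise ValueError(f"trial {i}: require_event set but trial has no event")
            offsets = offsets_all[(offsets_all <= ev) & (ev < offsets_all + win)]
            if len(offsets) == 0:
                raise ValueError(f"trial {i}: no crop offset contains the event at {ev}")
        windows = np.lib.stride_tricks.sliding_window_view(ts.data[i], win, axis=0)
        pieces.append(windows[offsets].transpose(0, 2, 1))
        k = len(offsets)
        labs.append(np.repeat(ts.labels[i], k))
        subs.append(np.repeat(ts.subject_ids[i], k))
        tasks.append(np.repeat(ts.task_ids[i], k))
        evs.append((ev - offsets) if ev != NO_EVENT else np.full(k, NO_EVENT))
    if not pieces:
        return TrialSet(
            np.empty((0, win, ts.n_channels)),
            np.empty(0, dtype=ts.labels.dtype),
            np.empty(0, dtype=ts.subject_ids.dtype),
            np.empty(0, dtype=ts.task_ids.dtype),
            np.empty(0, dtype=np.int64),
            ts.sampling_rate,
        )
    return TrialSet(
        np.concatenate(pieces),
        np.concatenate(labs),
        np.concatenate(subs),
        np.concatenate(tasks),
        np.concatenate(evs).astype(np.int64),
        ts.sampling_rate,
    )
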