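"""Synthetic multichannel-trial generator.

Emulates the statistical structure the decoding method assumes of
encephalographic recordings: a zero-mean background with power spectral
density falling off as 1/f^exponent, and class-dependent band-limited
oscillatory power concentrated in a subset of channels.  Subjects carry small
random per-channel gain offsets so that subject-wise evaluation is genuinely
harder than trial-wise evaluation.

The background is synthesized in the frequency domain — spectral amplitudes
proportional to f^(-exponent/2) with uniformly random phases, inverse
transformed, then scaled so the per-channel variance is exactly
``noise_sd**2`` (Parseval; the amplitudes are deterministic, so the variance
is analytic, not estimated).  A class effect with amplitude multiplier m adds
a sinusoid whose power equals (m - 1) times the background power inside the
effect band, so the band power of affected trials is m times that of
unaffected ones in expectation, and m = 1 is exactly "no effect".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import NO_EVENT, TrialSet

__all__ = [
    "ClassEffect",
    "SynthSpec",
    "generate_trialset",
    "generate_baselines",
    "band_separated_spec",
]


@dataclass(frozen=True)
class ClassEffect:
    """Band-limited oscillatory power added to trials of one class.

    band is (low, high) in Hz; channels are channel indices carrying the
    effect; amplitude is the band-power multiplier m (> 0, 1 = none);
    post_event_only restricts the oscillation to samples at/after the event.
    """

    label: int
    band: tuple
    channels: tuple
    amplitude: float
    post_event_only: bool = False


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic dataset.

    Defaults mirror the geometry of a whole-head MEG study: 151 channels at
    200 Hz, 3.5 s trials with the cue onset 1.5 s in.
    """

    n_subjects: int = 24
    trials_per_subject: int = 40
    n_channels: int = 151
    sampling_rate: float = 200.0
    trial_duration: float = 3.5
    event_time: float = 1.5
    spectral_exponent: float = 1.0
    class_effects: tuple = ()
    label_rule: str = "split_half"  # subject -> class: first half 0, second half 1
    n_classes: int = 2
    n_tasks: int = 1
    noise_sd: float = 1.0
    subject_gain_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.event_time < self.trial_duration):
            raise ValueError("event_time must lie strictly within trial_duration")
        if self.n_subjects < 1 or self.trials_per_subject < 1 or self.n_channels < 1:
            raise ValueError("n_subjects, trials_per_subject, n_channels must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for eff in self.class_effects:
            if eff.amplitude <= 0:
                raise ValueError(f"class_effects: amplitude must be > 0, got {eff.amplitude}")
            for c in eff.channels:
                if not (0 <= c < self.n_channels):
                    raise ValueError(f"class_effects: channel {c} >= n_channels={self.n_channels}")
            lo, hi = eff.band
            if not (0 < lo < hi <= self.sampling_rate / 2):
                raise ValueError(f"class_effects: band {eff.band} invalid for rate")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    @property
    def event_index(self) -> int:
        return int(round(self.event_time * self.sampling_rate))

    def subject_label(self, subject: int) -> int:
        if self.label_rule == "split_half":
            return int(subject >= self.n_subjects / 2)
        if self.label_rule == "modulo":
            return subject % self.n_classes
        raise ValueError(f"unknown label_rule {self.label_rule!r}")


# ---------------------------------------------------------------------------


def _spectral_amplitudes(n_samples: int, sampling_rate: float, exponent: float) -> np.ndarray:
    """rfft-bin amplitudes proportional to f^(-exponent/2); DC = 0."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    amps = np.zeros_like(freqs)
    amps[1:] = freqs[1:] ** (-exponent / 2.0)
    return amps


def one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple,
    n_samples: int,
    sampling_rate: float,
    exponent: float = 1.0,
    sd: float = 1.0,
) -> np.ndarray:
    """Zero-mean 1/f^exponent background; last-but-one axis is time.

    ``shape`` gives leading axes; output has shape ``shape + (n_samples,)``
    and per-series variance exactly ``sd**2``.
    """
    amps = _spectral_amplitudes(n_samples, sampling_rate, exponent)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=shape + (len(amps),))
    spec = amps * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    # Parseval: per-series variance of irfft of known amplitudes (real signal,
    # one-sided spectrum; Nyquist bin treated as ordinary — negligible power).
    var = 2.0 * np.sum(amps**2) / n_samples**2
    return x * (sd / np.sqrt(var))


def band_power_fraction(spec: SynthSpec, band: tuple) -> float:
    """Fraction of background power inside ``band`` (analytic, discrete bins)."""
    amps = _spectral_amplitudes(spec.n_samples, spec.sampling_rate, spec.spectral_exponent)
    freqs = np.fft.rfftfreq(spec.n_samples, d=1.0 / spec.sampling_rate)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.sum(amps[inside] ** 2) / np.sum(amps**2))


def _effect_waveform(
    rng: np.random.Generator, spec: SynthSpec, eff: ClassEffect, event_index: int
) -> np.ndarray:
    """One trial's oscillation on a single channel, shape (T,)."""
    t = np.arange(spec.n_samples) / spec.sampling_rate
    freq = rng.uniform(*eff.band)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    p_band = spec.noise_sd**2 * band_power_fraction(spec, eff.band)
    amp = np.sqrt(2.0 * max(eff.amplitude - 1.0, 0.0) * p_band)
    wave = amp * np.sin(2.0 * np.pi * freq * t + phase)
    env = np.ones(spec.n_samples)
    if eff.post_event_only:
        env[:event_index] = 0.0
        ramp = min(int(round(0.05 * spec.sampling_rate)), spec.n_samples - event_index)
        if ramp > 1:
            env[event_index : event_index + ramp] = 0.5 * (
                1 - np.cos(np.pi * np.arange(ramp) / ramp)
            )
    return wave * env


def _subject_gains(spec: SynthSpec) -> np.ndarray:
    """Per-subject per-channel gain offsets, shared by trials and baselines."""
    rng = np.random.default_rng([spec.seed, 1715])
    return 1.0 + rng.uniform(
        -spec.subject_gain_jitter, spec.subject_gain_jitter, size=(spec.n_subjects, spec.n_channels)
    )


def generate_trialset(spec: SynthSpec) -> TrialSet:
    """Draw a full synthetic dataset; identical spec + seed => identical arrays."""
    rng = np.random.default_rng(spec.seed)
    n_trials = spec.n_subjects * spec.trials_per_subject
    T, C = spec.n_samples, spec.n_channels
    data = np.empty((n_trials, T, C))
    labels = np.empty(n_trials, dtype=np.int64)
    subjects = np.empty(n_trials, dtype=np.int64)
    tasks = np.empty(n_trials, dtype=np.int64)
    ev = spec.event_index

    gains = _subject_gains(spec)
    i = 0
    for s in range(spec.n_subjects):
        label = spec.subject_label(s)
        for k in range(spec.trials_per_subject):
            bg = one_over_f_noise(
                rng, (C,), T, spec.sampling_rate, spec.spectral_exponent, spec.noise_sd
            ).T  # (T, C)
            trial = bg * gains[s]
            for eff in spec.class_effects:
                if eff.label != label:
                    continue
                for c in eff.channels:
                    trial[:, c] += _effect_waveform(rng, spec, eff, ev)
            data[i] = trial
            labels[i] = label
            subjects[i] = s
            tasks[i] = k % spec.n_tasks
            i += 1
    return TrialSet(
        data, labels, subjects, np.asarray(tasks), np.full(n_trials, ev), spec.sampling_rate
    )


def band_separated_spec(seed: int = 0) -> SynthSpec:
    """Reference parameter-recovery dataset: two classes separated by band.

    24 subjects x 40 trials of 2 s at 200 Hz over 32 channels; class 0
    carries an 8-12 Hz effect and class 1 an 18-22 Hz effect, each doubling
    band power (x2 amplitude) on the first 8 channels.
    """
    channels = tuple(range(8))
    return SynthSpec(
        n_subjects=24,
        trials_per_subject=40,
        n_channels=32,
        sampling_rate=200.0,
        trial_duration=2.0,
        event_time=0.5,
        class_effects=(
            ClassEffect(0, (8.0, 12.0), channels, 2.0),
            ClassEffect(1, (18.0, 22.0), channels, 2.0),
        ),
        seed=seed,
    )


def generate_baselines(spec: SynthSpec, duration: float) -> TrialSet:
    """One event-free background recording per subject per task.

    Same channel count and sampling rate as the trials; no class effect;
    event index marked absent.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(spec.seed + 1)
    T = int(round(duration * spec.sampling_rate))
    n = spec.n_subjects * spec.n_tasks
    data = np.empty((n, T, spec.n_channels))
    subjects = np.empty(n, dtype=np.int64)
    tasks = np.empty(n, dtype=np.int64)
    labels = np.empty(n, dtype=np.int64)
    gains = _subject_gains(spec)
    i = 0
    for s in range(spec.n_subjects):
        for task in range(spec.n_tasks):
            bg = one_over_f_noise(
                rng,
                (spec.n_channels,),
                T,
                spec.sampling_rate,
                spec.spectral_exponent,
                spec.noise_sd,
            ).T
            data[i] = bg * gains[s]
            subjects[i] = s
            tasks[i] = task
            labels[i] = spec.subject_label(s)
            i += 1
    return TrialSet(
        data, labels, subjects, tasks, np.full(n, NO_EVENT, dtype=np.int64), spec.sampling_rate
    )
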