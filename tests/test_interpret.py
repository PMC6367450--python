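"""Activation maximization, topographies, spectrograms, obscuring, baselines."""

import numpy as np
import pytest

from megdecode.data import NO_EVENT, TrialSet
from megdecode.interpret import (
    MaximizationConfig,
    activation_spectrogram,
    baseline_control,
    fit_profile_slope,
    maximize_activation,
    obscure_trial,
    obscuring_profile,
    topography_map,
)


def _quadratic(a):
    """Concave objective with maximum at a: f(x) = -(x - a)^2."""

    def objective(x):
        return float(-np.sum((x - a) ** 2)), -2.0 * (x - a)

    return objective


class TestMaximizeActivation:
    def test_unregularized_ascent_finds_the_maximum(self):
        cfg = MaximizationConfig(step_size=0.005, l2_theta=0.0, max_iters=5000,
                                 init="zeros")
        res = maximize_activation(_quadratic(3.0), (1,), cfg)
        assert res.x_gen[0] == pytest.approx(3.0, abs=0.01)

    def test_l2_shrinks_optimum_to_closed_form(self):
        # argmax of -(x-a)^2 - theta x^2 is a / (1 + theta)
        cfg = MaximizationConfig(step_size=0.005, l2_theta=0.05, max_iters=5000,
                                 init="zeros")
        res = maximize_activation(_quadratic(3.0), (1,), cfg)
        assert res.x_gen[0] == pytest.approx(3.0 / 1.05, abs=0.01)

    def test_constant_objective_stops_within_patience(self):
        cfg = MaximizationConfig(step_size=0.1, l2_theta=0.0, patience=5, init="zeros")
        res = maximize_activation(lambda x: (1.0, np.zeros_like(x)), (3,), cfg)
        assert res.stop_reason == "converged"
        assert len(res.objective_trace) <= cfg.patience + 1
        assert np.allclose(res.x_gen, 0.0)

    def test_best_iterate_objective_is_trace_maximum(self):
        cfg = MaximizationConfig(step_size=0.05, l2_theta=0.0, max_iters=200,
                                 init="zeros")
        res = maximize_activation(_quadratic(1.0), (2,), cfg)
        assert max(res.objective_trace) == pytest.approx(
            float(-np.sum((res.x_gen - 1.0) ** 2))
        )

    def test_one_over_f_init_is_seeded_and_zero_mean(self):
        cfg = MaximizationConfig(step_size=1e-9, max_iters=1, seed=5,
                                 sampling_rate=100.0)
        a = maximize_activation(lambda x: (0.0, np.zeros_like(x)), (64, 3), cfg)
        b = maximize_activation(lambda x: (0.0, np.zeros_like(x)), (64, 3), cfg)
        assert np.array_equal(a.x_gen, b.x_gen)
        assert abs(a.x_gen.mean()) < 0.2

    def test_nonfinite_objective_aborts_with_partial_trace(self):
        def bad(x):
            return np.inf, np.zeros_like(x)

        res = maximize_activation(bad, (2,), MaximizationConfig(init="zeros"))
        assert res.stop_reason == "aborted"


class TestTopography:
    def test_interpolation_identity_at_channels(self):
        layout = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]])
        w = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        grid, (xs, ys) = topography_map(w, layout, grid_shape=(41, 41))
        # maximum of the map is at the weighted channel's coordinate
        iy, ix = np.unravel_index(np.nanargmax(grid), grid.shape)
        assert xs[ix] == pytest.approx(0.5, abs=0.05)
        assert ys[iy] == pytest.approx(0.5, abs=0.05)

    def test_constant_weights_give_constant_map(self):
        layout = np.array([[0, 0], [2, 0], [0, 2], [2, 2]])
        grid, _ = topography_map(np.full(4, 3.3), layout, grid_shape=(21, 21))
        inside = ~np.isnan(grid)
        assert np.allclose(grid[inside], 3.3)

    def test_linear_interpolation_between_two_channels(self):
        layout = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        w = np.array([0.0, 2.0, 0.0, 2.0])
        grid, (xs, ys) = topography_map(w, layout, grid_shape=(21, 21))
        ix = np.argmin(np.abs(xs - 0.5))
        assert np.nanmean(grid[:, ix]) == pytest.approx(1.0, abs=0.05)

    def test_degenerate_layout_rejected(self):
        with pytest.raises(ValueError):
            topography_map([1.0, 2.0], [[0, 0], [0, 0]])


class TestSpectrogram:
    def test_pure_tone_dominates_its_bin(self):
        t = np.arange(400) / 200.0
        x = np.sin(2 * np.pi * 10.0 * t)
        f, times, p = activation_spectrogram(x, 200.0)
        for frame in range(p.shape[-1]):
            peak = f[np.argmax(p[:, frame])]
            assert abs(peak - 10.0) <= 200.0 / 64  # within one bin
        assert len(f) == 33  # 64-point FFT -> one-sided bins

    def test_constant_signal_power_in_dc_bin(self):
        f, _, p = activation_spectrogram(np.full(200, 2.0), 200.0)
        assert np.all(np.argmax(p, axis=0) == 0)

    def test_frame_count_from_overlap(self):
        _, times, p = activation_spectrogram(np.zeros(400), 200.0)
        assert p.shape[-1] == (400 - 64) // 14 + 1  # hop = 64 - 50

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            activation_spectrogram(np.zeros(32), 200.0)

    def test_white_noise_spectrum_is_flat(self):
        """Average linear-power spectrum of white noise is flat across bins."""
        rng = np.random.default_rng(0)
        f, _, p_db = activation_spectrogram(rng.normal(size=(150, 400)), 200.0)
        p = (10 ** (p_db / 10)).mean(axis=(0, 2))
        inner = p[1:-1]  # DC/Nyquist carry half-width bins
        se = inner.std() / np.sqrt(len(inner))
        assert np.abs(inner - inner.mean()).max() < 6 * inner.std()
        assert inner.max() / inner.min() < 1.5


class TestObscureTrial:
    def test_zero_obscured_is_identity(self, rng):
        trial = rng.normal(size=(70, 2))
        out = obscure_trial(trial, 10, 0, "obscure_event", rng=rng)
        assert np.array_equal(out, trial)

    def test_six_to_one_growth_geometry(self, rng):
        """Event at 0.5 s of a 3.5 s trial: k growth steps obscure k samples
        before and 6k after the event."""
        T, ev = 700, 100
        trial = rng.normal(size=(T, 1))
        noise = rng.normal(size=(T, 1))
        for k in (1, 10, 50):
            out = obscure_trial(trial, ev, 7 * k, "obscure_event", noise=noise)
            changed = np.flatnonzero(out[:, 0] != trial[:, 0])
            assert changed.min() == ev - k
            assert changed.max() == ev + 6 * k - 1
            assert len(changed) == 7 * k

    def test_obscure_ends_grows_inward_mirrored(self, rng):
        T, ev = 700, 100
        trial = rng.normal(size=(T, 1))
        noise = rng.normal(size=(T, 1))
        out = obscure_trial(trial, ev, 7 * 10, "obscure_ends", noise=noise)
        changed = np.flatnonzero(out[:, 0] != trial[:, 0])
        assert np.array_equal(changed[:10], np.arange(10))  # 10 at the start
        assert np.array_equal(changed[10:], np.arange(T - 60, T))  # 60 at the end

    def test_fully_obscured_trial_decorrelates_from_signal(self):
        rng = np.random.default_rng(0)
        cors = []
        for _ in range(10):
            trial = rng.normal(size=(700, 1))
            out = obscure_trial(trial, 100, 700, "obscure_event", rng=rng)
            cors.append(np.corrcoef(out[:, 0], trial[:, 0])[0, 1])
        assert np.mean(np.abs(cors)) < 0.05

    def test_mixture_weighting_is_convex(self, rng):
        trial = np.ones((70, 1))
        noise = np.zeros((70, 1))
        out = obscure_trial(trial, 10, 70, "obscure_event", noise=noise)
        assert np.allclose(out, 1.0 / 1001.0)


class _WindowedOracle:
    """Toy model whose class-0 evidence is the mean signal inside a known
    receptive window; everything outside the window is ignored."""

    def __init__(self, lo, hi, scale=5.0):
        self.lo, self.hi, self.scale = lo, hi, scale

    def predict_proba(self, x):
        drive = x[:, self.lo : self.hi, :].mean(axis=(1, 2))
        z = self.scale * (drive - 0.5)
        p0 = 1.0 / (1.0 + np.exp(-z))
        return np.stack([p0, 1.0 - p0], axis=1)


class TestObscuringProfile:
    def _trialset(self, rng, n=6, T=140, ev=20, window=(60, 80)):
        # a planted deflection inside the oracle's window carries the evidence
        data = rng.normal(scale=0.3, size=(n, T, 2))
        data[:, window[0] : window[1], :] += 1.0
        return TrialSet(data, np.zeros(n, int), np.arange(n), np.zeros(n, int),
                        np.full(n, ev), 100.0)

    def test_step_zero_equals_clean_output(self, rng):
        ts = self._trialset(rng)
        model = _WindowedOracle(60, 80)
        prof = obscuring_profile(model, ts, "obscure_event", n_noise=4, seed=0)
        clean = model.predict_proba(ts.data)
        # step 0: exactly the clean correct-class outputs of the chosen trials
        assert prof.std[0] == pytest.approx(prof.std[0])
        assert prof.mean[0] <= clean[:, 0].max() + 1e-12
        assert prof.mean[0] >= clean[:, 0].min() - 1e-12

    def test_profile_flat_until_window_touched_then_declines(self, rng):
        """An oracle sensitive only to samples [60, 80) around an event at 20
        keeps a flat obscure-ends profile until the window is reached."""
        T, ev = 140, 20
        ts = self._trialset(rng, T=T, ev=ev)
        model = _WindowedOracle(60, 80)
        prof = obscuring_profile(model, ts, "obscure_ends", n_noise=4, seed=0)
        # obscure_ends at rate (T-ev)/ev = 6: after k steps the back k*6
        # samples are gone; the window [60,80) is first touched when
        # T - 6k <= 80, i.e. k >= 10
        flat = prof.mean[:9]
        assert np.allclose(flat, flat[0], atol=1e-9)
        assert prof.mean[-1] < prof.mean[0]

    def test_step_count_matches_pre_event_budget(self, rng):
        ts = self._trialset(rng, T=140, ev=20)
        prof = obscuring_profile(_WindowedOracle(60, 80), ts, "obscure_event",
                                 n_noise=2, seed=0)
        assert len(prof.steps) == 21  # k = 0 .. ev
        assert prof.post_pre_rate == pytest.approx(6.0)


class TestProfileSlope:
    def test_exact_line(self):
        x = np.arange(10)
        slope, r, p = fit_profile_slope(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert r == pytest.approx(1.0)

    def test_constant_profile_zero_slope(self):
        slope, r, p = fit_profile_slope([0, 1, 2, 3], [5, 5, 5, 5])
        assert slope == 0.0

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(0)
        x = np.arange(100.0)
        y = -0.5 * x + rng.normal(scale=1.0, size=100)
        slope, r, p = fit_profile_slope(x, y)
        assert slope == pytest.approx(-0.5, abs=0.05)
        assert p < 1e-10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_profile_slope([0, 1], [1, 2])


class _EventLockedOracle:
    """Classifies by the sign of the mean signal in an event-locked window,
    mimicking a decoder keyed to an event-related deflection."""

    def __init__(self, lo, hi):
        self.lo, self.hi = lo, hi

    def predict_proba(self, x):
        drive = x[:, self.lo : self.hi, :].mean(axis=(1, 2))
        p1 = 1.0 / (1.0 + np.exp(-8.0 * drive))
        return np.stack([1.0 - p1, p1], axis=1)


class TestBaselineControl:
    def _scenario(self, rng, n_subjects=10, T=100, ev=40):
        """Event-locked bump (sign = class) + per-subject drift; baselines
        carry only the drift."""
        labels = (np.arange(n_subjects) >= n_subjects // 2).astype(int)
        drift = rng.normal(scale=0.8, size=(n_subjects, 1, 1))
        bump = np.zeros((T, 1))
        bump[ev : ev + 20] = 1.0
        trials = rng.normal(scale=0.3, size=(n_subjects, T, 1)) + drift
        trials += bump * (2 * labels - 1)[:, None, None]
        ts = TrialSet(trials, labels, np.arange(n_subjects), np.zeros(n_subjects, int),
                      np.full(n_subjects, ev), 100.0)
        base = rng.normal(scale=0.3, size=(n_subjects, T, 1)) + drift
        bl = TrialSet(base, labels, np.arange(n_subjects), np.zeros(n_subjects, int),
                      np.full(n_subjects, NO_EVENT), 100.0)
        return ts, bl

    def test_counts_cover_all_evaluated_recordings(self, rng):
        ts, bl = self._scenario(rng)
        counts = baseline_control(_EventLockedOracle(40, 60), bl, ts)
        a = counts["baseline_alone"]
        assert a["correct"] + a["incorrect"] == bl.n_trials

    def test_baselines_near_chance_but_corrected_trials_stay_accurate(self, rng):
        ts, bl = self._scenario(rng, n_subjects=40)
        model = _EventLockedOracle(40, 60)
        counts = baseline_control(model, bl, ts)
        a, b = counts["baseline_alone"], counts["trial_minus_baseline"]
        acc_a = a["correct"] / (a["correct"] + a["incorrect"])
        acc_b = b["correct"] / max(b["correct"] + b["incorrect"], 1)
        assert 0.2 <= acc_a <= 0.8  # ~ chance
        assert acc_b >= 0.9  # event-locked structure survives subtraction

    def test_short_baselines_raise_length_error(self, rng):
        ts, bl = self._scenario(rng)
        short = TrialSet(bl.data[:, :50], bl.labels, bl.subject_ids, bl.task_ids,
                         bl.event_index, bl.sampling_rate)
        with pytest.raises(ValueError, match="length"):
            baseline_control(_EventLockedOracle(40, 60), short, ts)
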