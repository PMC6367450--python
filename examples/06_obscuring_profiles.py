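"""Obscuring profiles: which part of the trial does a model rely on?

Uses a toy model keyed to a known event-locked window so the expected
profile is unambiguous: obscuring from the trial ends leaves the output flat
until the growth (6 post-event samples per pre-event sample for an event at
0.5 s of a 3.5 s geometry scaled down here) reaches the window, then the
output falls.  A slope is fitted to the declining segment.
"""

import numpy as np

from megdecode import TrialSet
from megdecode.interpret import fit_profile_slope, obscuring_profile

rng = np.random.default_rng(0)
T, ev, win = 140, 20, (60, 80)
data = rng.normal(scale=0.3, size=(8, T, 2))
data[:, win[0]:win[1], :] += 1.0  # the event-locked deflection the model reads
ts = TrialSet(data, np.zeros(8, int), np.arange(8), np.zeros(8, int),
              np.full(8, ev), 100.0)


class WindowedModel:
    """Outputs class-0 probability from the mean signal in samples 60-80."""

    def predict_proba(self, x):
        drive = x[:, win[0]:win[1], :].mean(axis=(1, 2))
        p0 = 1.0 / (1.0 + np.exp(-5.0 * (drive - 0.5)))
        return np.stack([p0, 1.0 - p0], axis=1)


prof = obscuring_profile(WindowedModel(), ts, schedule="obscure_ends",
                         n_noise=10, seed=0)
print(f"growth rate: {prof.post_pre_rate:.0f} end samples per start sample; "
      f"{len(prof.steps)} growth steps")
print(f"clean output {prof.mean[0]:.3f}; flat until step ~10, "
      f"final output {prof.mean[-1]:.3f}")

decline = slice(10, None)
slope, r, p = fit_profile_slope(np.arange(len(prof.steps))[decline], prof.mean[decline])
print(f"declining-segment regression: slope {slope:.4f} per step, r = {r:.3f}, p = {p:.2e}")
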