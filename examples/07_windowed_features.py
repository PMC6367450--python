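"""The classical windowed-feature pipeline and correlation-based selection.

Extracts per-window summary and spectral features (including the circular
autocorrelation computed through the FFT), then selects columns correlated
with a continuous target under a Bonferroni-corrected threshold plus an |r|
floor.  A 2 s epoch with 50 ms windows at 25 ms overlap yields 79 windows.
"""

import numpy as np

from megdecode import SelectionRule, SynthSpec, WindowPlan, acf
from megdecode.features import assemble_features, plan_windows, select_features
from megdecode.synthgen import ClassEffect, generate_trialset

plan = WindowPlan(window_length=50.0, overlap=25.0)
print(f"windows per 2000 ms epoch: {len(plan_windows(2000.0, plan))}")

w = np.array([1.0, 0.0, 0.0, 0.0])
print(f"circular ACF of a delta window: {acf(w).round(6)}")

spec = SynthSpec(n_subjects=6, trials_per_subject=40, n_channels=4,
                 sampling_rate=200.0, trial_duration=2.0, event_time=0.5,
                 class_effects=(ClassEffect(1, (8.0, 12.0), (0,), 4.0),), seed=5)
ts = generate_trialset(spec)
table = assemble_features(ts, plan, kinds=("rms", "variance", "log_energy"))
print(f"feature table: {table.matrix.shape[0]} trials x {table.matrix.shape[1]} features")

sel, rs, ps = select_features(table, ts.labels.astype(float),
                              SelectionRule(alpha=1e-3, r_min=0.2))
print(f"selected {len(sel)} features; strongest |r| = {np.nanmax(np.abs(rs)):.3f}")
on_effect_channel = [n for n in (table.names[i] for i in sel) if n.startswith("c0_")]
print(f"{len(on_effect_channel)} of them come from the channel carrying the band effect")
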