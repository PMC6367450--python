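"""Minimal preprocessing chain and cropped-trial augmentation.

Epochs a continuous recording around cue onsets (-1.5 s to +2 s), band-pass
filters it, and multiplies each 3.5 s trial into 2 s crops that all contain
the event.  At 200 Hz and stride 1 the crop count is 300 per trial — the
augmentation ratio of the reference pipeline.
"""

import numpy as np

from megdecode import CropPlan, bandpass, crop_augment, epoch

rng = np.random.default_rng(0)
rate = 200.0
recording = rng.normal(size=(int(60 * rate), 4))  # 60 s, 4 channels
cues = np.arange(5.0, 55.0, 5.0)  # ten cues

trials = epoch(recording, rate, cues, pre=1.5, post=2.0)
print(f"epoched: {trials.n_trials} trials of {trials.n_samples} samples, "
      f"event at sample {trials.event_index[0]}")

trials = bandpass(trials, 0.5, 99.0)
crops = crop_augment(trials, CropPlan(window_length=2.0, stride=1, require_event=True))
print(f"after augmentation: {crops.n_trials} crops "
      f"({crops.n_trials // trials.n_trials} per trial, window {crops.n_samples} samples)")
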