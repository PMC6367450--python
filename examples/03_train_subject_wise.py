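"""Subject-wise cross-validated SCNN training on synthetic band-separated data.

A scaled-down version of the package's reference experiment: subjects of the
two classes differ only in which band (8-12 vs 18-22 Hz) carries doubled
power.  Trials of held-out test subjects are never seen during training, so
the test accuracy printed per fold measures recovery of the band rule on
unseen subjects (chance = 0.5).  Runs in a couple of minutes; the full-size
experiment lives in megdecode.recipes.run_parameter_recovery.
"""

from dataclasses import replace

import numpy as np

from megdecode.recipes import reference_scnn_config, reference_train_config
from megdecode.synthgen import band_separated_spec, generate_trialset
from megdecode.training import assign_folds, train_model

spec = replace(band_separated_spec(seed=1), n_subjects=16, trials_per_subject=40)
ts = generate_trialset(spec)
subs, counts = np.unique(ts.subject_ids, return_counts=True)
plan = assign_folds(dict(zip(subs.tolist(), counts.tolist())), n_folds=3,
                    test_subjects=[0, 8])
print("fold totals:", plan.fold_totals, " test subjects:", sorted(plan.test_subjects))

results = train_model(reference_scnn_config(seed=1), ts, plan,
                      reference_train_config(seed=1, epochs=60))
for r in results:
    print(f"fold {r.fold}: validation {r.val_accuracy:.3f}  held-out test {r.test_accuracy:.3f}")
print(f"mean held-out accuracy: {np.mean([r.test_accuracy for r in results]):.3f}")
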