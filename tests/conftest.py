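import numpy as np
import pytest

from megdecode.data import TrialSet
from megdecode.synthgen import ClassEffect, SynthSpec, generate_trialset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_spec():
    """A fast-to-generate dataset with a strong 8-12 Hz class contrast."""
    return SynthSpec(
        n_subjects=4,
        trials_per_subject=5,
        n_channels=6,
        sampling_rate=100.0,
        trial_duration=1.0,
        event_time=0.3,
        class_effects=(ClassEffect(1, (8.0, 12.0), (0, 1), 3.0),),
        seed=7,
    )


@pytest.fixture()
def tiny_trialset(tiny_spec):
    return generate_trialset(tiny_spec)


@pytest.fixture()
def random_trialset(rng):
    """Structureless trials for plumbing tests."""
    n, T, C = 12, 50, 3
    return TrialSet(
        rng.normal(size=(n, T, C)),
        rng.integers(0, 2, n),
        np.repeat(np.arange(4), 3),
        np.zeros(n, dtype=int),
        np.full(n, 20),
        100.0,
    )
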